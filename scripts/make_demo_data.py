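"""Regenerate the committed demo data under src/barcodiag/data/.

Run from the repository root:

    python scripts/make_demo_data.py

The demo is fully determined by ``barcodiag.simulate.DEMO_SEED``; this
script exists so the committed files can be audited and reproduced.
"""

from pathlib import Path

from barcodiag import io
from barcodiag.simulate import DEMO_SEED, build_krai_krue_demo

DATA = Path(__file__).resolve().parent.parent / "src" / "barcodiag" / "data"


def main() -> None:
    DATA.mkdir(exist_ok=True)
    panel, alignment, truth, primer_panel = build_krai_krue_demo(DEMO_SEED)
    io.write_alignment(alignment, DATA / "krai_krue_demo_aligned.fasta")
    (DATA / "krai_krue_demo_truth.json").write_text(truth.to_json() + "\n")
    io.write_primer_panel(primer_panel, DATA / "krai_krue_demo_panel.json")
    print(f"demo data written to {DATA} (seed {DEMO_SEED})")


if __name__ == "__main__":
    main()
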