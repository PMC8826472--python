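#!/usr/bin/env python
"""Render the human-readable summary of the pipeline run.

Formats the subject accounting, the BMI-group comparison grid and the two
prevalence-ratio model tables from results/run/ into results/run/report.md.
"""

from pathlib import Path

from circstrain.pipeline import make_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = make_report(ROOT / "results" / "run")
    print(f"wrote {out}")
    print(Path(out).read_text())


if __name__ == "__main__":
    main()
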