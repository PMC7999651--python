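"""Render the demographic and PK summary tables (CSV + Markdown).

Re-reads the persisted analysis dataset so every printed number is
recomputable from the intermediate files, and writes the stratified
summaries (sex, trial, ezetimibe, race, SLCO1B1 phenotype, CYP3A5 genotype)
under results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd

from statinpgx import io
from statinpgx.reporting import (DEMO_SUMMARY_COLUMNS, PK_SUMMARY_COLUMNS,
                                 group_summary, render_markdown)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path,
                    default=Path("results/stats/analysis_dataset.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    dataset = pd.read_csv(args.dataset, comment="#")
    args.out.mkdir(parents=True, exist_ok=True)

    tables = {
        "demographics_by_sex": ("sex", DEMO_SUMMARY_COLUMNS),
        "demographics_by_race": ("race_merged", DEMO_SUMMARY_COLUMNS),
        "pk_by_sex": ("sex", PK_SUMMARY_COLUMNS),
        "pk_by_trial": ("trial_arm", PK_SUMMARY_COLUMNS),
        "pk_by_slco1b1": ("slco1b1_phenotype", PK_SUMMARY_COLUMNS),
        "pk_by_cyp3a5": ("cyp3a5_genotype", PK_SUMMARY_COLUMNS),
    }
    md = []
    for name, (strat, cols) in tables.items():
        summary = group_summary(dataset, strat, cols)
        io._write_with_header(summary, args.out / f"{name}.csv")
        md.append(render_markdown(summary, name))
    (args.out / "tables.md").write_text("\n".join(md))

    slco = group_summary(dataset, "slco1b1_phenotype", ["auc_dw"])
    print(slco[["level", "n", "auc_dw", "auc_dw_cv"]].round(1).to_string(index=False))
    print(f"wrote {len(tables)} summary tables to {args.out}/")


if __name__ == "__main__":
    main()
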