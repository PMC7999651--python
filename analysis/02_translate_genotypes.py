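"""Translate panel genotypes into star-allele diplotypes and phenotypes.

Reads results/cohort/genotypes.csv, imputes missing calls as homozygous
reference, and writes per-subject-per-gene assignments to
results/phenotypes.csv.
"""

import argparse
from pathlib import Path

from statinpgx import io, pgx


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genotypes", type=Path,
                    default=Path("results/cohort/genotypes.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/phenotypes.csv"))
    args = ap.parse_args()

    genotypes = io.read_genotypes_csv(args.genotypes)
    wide, long = pgx.translate_cohort(genotypes)
    io.write_phenotypes_csv(long, args.out)

    slco = wide["slco1b1_phenotype"].value_counts().to_dict()
    cyp = wide["cyp3a5_genotype"].value_counts().to_dict()
    n_imputed = (long["imputed_rsids"] != "").sum()
    print(f"translated {wide.shape[0]} subjects; SLCO1B1 {slco}; CYP3A5 {cyp}")
    print(f"{n_imputed} gene-level assignments involved imputed calls")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
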