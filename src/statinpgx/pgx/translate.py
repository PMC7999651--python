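"""Genotype → star-allele diplotype → phenotype translation.

All allele-definition content (panel variants, per-gene rules, diplotype
maps, activity cutpoints) is loaded from versioned TSV data files; no star
allele or cutpoint is hard-coded here.  Missing or failed genotype calls are
imputed as homozygous reference ("not mutated") and the imputation is
recorded on the resulting assignment.

Phasing convention: when several heterozygous single-variant alleles are
observed for one gene, the variants are assumed to lie in trans (one star
allele copy each).  If more than two variant allele copies accumulate, the
two most deleterious are retained and the assignment is flagged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

MISSING_TOKENS = {".", "", "fail", "failed", "nan", "na"}
FUNCTION_RANK = {"no": 0, "decreased": 1, "normal": 2, "increased": 3,
                 "annotation": 9}

#: the 3-SNP ABCB1 subset reported to dominate transporter activity
ABCB1_CORE_RSIDS = ("rs1045642", "rs2032582", "rs1128503")

#: analysis stratifier -> column of the wide phenotype table
STRATIFIER_COLUMN = {
    "SLCO1B1": "slco1b1_phenotype",
    "CYP3A5": "cyp3a5_genotype",
    "SLC22A1*2": "slc22a1_star2",
    "SLC22A1*5": "slc22a1_star5",
    "UGT2B7": "ugt2b7",
}


@dataclass
class PhenotypeAssignment:
    subject_id: str
    gene: str
    diplotype: str
    phenotype: str
    activity_score: float | None = None
    imputed_calls: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Definitions:
    """Parsed allele-definition tables."""

    panel: pd.DataFrame       # one row per rsid
    genes: pd.DataFrame       # one row per gene
    phenotype_map: dict       # (gene, diplotype) -> phenotype
    cutpoints: pd.DataFrame

    @property
    def rsids(self) -> set[str]:
        return set(self.panel["rsid"])

    def gene_rsids(self, gene: str, phenotype_only: bool = False) -> list[str]:
        sub = self.panel[self.panel["gene"] == gene]
        if phenotype_only:
            sub = sub[sub["used_in_phenotype"] == "yes"]
        return list(sub["rsid"])

    def reference_allele(self, gene: str) -> str:
        return self.genes.loc[gene, "reference_allele"]

    def rule(self, gene: str) -> str:
        return self.genes.loc[gene, "rule"]


def _read_tsv(name: str) -> pd.DataFrame:
    path = resources.files("statinpgx.pgx") / "data" / name
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)


@lru_cache(maxsize=1)
def load_definitions() -> Definitions:
    panel = _read_tsv("panel.tsv")
    genes = _read_tsv("genes.tsv").set_index("gene")
    maps = _read_tsv("phenotype_maps.tsv")
    cutpoints = _read_tsv("activity_cutpoints.tsv")
    cutpoints["score_min"] = cutpoints["score_min"].astype(float)
    cutpoints["score_max"] = cutpoints["score_max"].astype(float)
    phenotype_map = {(r.gene, r.diplotype): r.phenotype for r in maps.itertuples()}
    if panel["rsid"].duplicated().any():
        raise ValueError("duplicate rsid in panel definition")
    per_gene = panel[panel["used_in_phenotype"] == "yes"].groupby("gene")["allele"]
    for gene, alleles in per_gene:
        if alleles.duplicated().any():
            raise ValueError(f"duplicate allele name for {gene}")
    return Definitions(panel=panel, genes=genes,
                       phenotype_map=phenotype_map, cutpoints=cutpoints)


def _star_key(name: str) -> tuple:
    """Deterministic ordering for star alleles: numeric part, then suffix."""
    m = re.match(r"\*(\d+)([A-Z]*)$", name)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, name)


def _normalize_diplotype(a1: str, a2: str) -> str:
    first, second = sorted((a1, a2), key=_star_key)
    return f"{first}/{second}"


# --- imputation -------------------------------------------------------------


def _is_missing(value) -> bool:
    return pd.isna(value) or str(value).strip().lower() in MISSING_TOKENS


def impute_missing(calls: pd.DataFrame, defs: Definitions | None = None,
                   subjects=None) -> pd.DataFrame:
    """Complete a long genotype table against the panel.

    Variants absent for a subject, and calls with a missing/failed allele,
    are replaced by the homozygous reference genotype and marked
    ``imputed=True``.  Unknown rsids are rejected by name.  The operation is
    idempotent.
    """
    defs = defs or load_definitions()
    calls = calls.copy()
    unknown = set(calls["rsid"]) - defs.rsids
    if unknown:
        raise ValueError(f"rsids not in panel: {sorted(unknown)}")

    panel = defs.panel.set_index("rsid")
    if subjects is None:
        subjects = calls["subject_id"].unique()

    if "imputed" not in calls.columns:
        calls["imputed"] = False
    missing_mask = calls["allele1"].map(_is_missing) | calls["allele2"].map(_is_missing)
    calls.loc[missing_mask, "allele1"] = panel.loc[
        calls.loc[missing_mask, "rsid"], "ref"].to_numpy()
    calls.loc[missing_mask, "allele2"] = panel.loc[
        calls.loc[missing_mask, "rsid"], "ref"].to_numpy()
    calls.loc[missing_mask, "imputed"] = True

    # add entirely absent (subject, rsid) pairs as reference homozygotes
    full = pd.MultiIndex.from_product(
        [subjects, panel.index], names=["subject_id", "rsid"]
    ).to_frame(index=False)
    merged = full.merge(calls, on=["subject_id", "rsid"], how="left")
    absent = merged["allele1"].isna()
    merged.loc[absent, "gene"] = panel.loc[merged.loc[absent, "rsid"], "gene"].to_numpy()
    merged.loc[absent, "allele1"] = panel.loc[merged.loc[absent, "rsid"], "ref"].to_numpy()
    merged.loc[absent, "allele2"] = panel.loc[merged.loc[absent, "rsid"], "ref"].to_numpy()
    merged.loc[absent, "imputed"] = True
    merged["imputed"] = merged["imputed"].astype(bool)
    return merged[["subject_id", "gene", "rsid", "allele1", "allele2", "imputed"]]


# --- diplotype calling ------------------------------------------------------


def _star_rows(defs: Definitions, gene: str) -> list[tuple[str, str, str]]:
    """(rsid, allele, function) for the gene's star-defining variants."""
    panel = defs.panel[(defs.panel["gene"] == gene)
                       & (defs.panel["used_in_phenotype"] == "yes")
                       & (defs.panel["function"] != "annotation")]
    return [(r.rsid, r.allele, r.function) for r in panel.itertuples()]


def _diplotype_from_copies(star_rows, copies_of, ref: str) -> tuple[str, list[str]]:
    """Core diplotype resolution from per-rsid alternate-allele copy counts."""
    flags: list[str] = []
    copies: list[tuple[str, str]] = []
    for rsid, allele, function in star_rows:
        copies.extend([(allele, function)] * copies_of(rsid))
    if len(copies) > 2:
        copies.sort(key=lambda c: (FUNCTION_RANK[c[1]], _star_key(c[0])))
        copies = copies[:2]
        flags.append("excess_variant_alleles")
    names = [c[0] for c in copies] + [ref] * (2 - len(copies))
    return _normalize_diplotype(names[0], names[1]), flags


def _subject_gene_calls(calls: pd.DataFrame, gene: str) -> pd.DataFrame:
    sub = calls[calls["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no calls for gene {gene}")
    return sub


def call_diplotype(gene: str, calls: pd.DataFrame,
                   defs: Definitions | None = None) -> tuple[str, list[str]]:
    """Star-allele diplotype from complete (imputed) calls for one subject.

    Returns ``(diplotype, flags)``.  Each alternate allele at a defining
    variant contributes one copy of that star allele; remaining copies are
    the gene's reference allele.
    """
    defs = defs or load_definitions()
    sub = _subject_gene_calls(calls, gene)
    by_rsid = sub.set_index("rsid")
    alt = dict(zip(defs.panel["rsid"], defs.panel["alt"]))

    def copies_of(rsid: str) -> int:
        if rsid not in by_rsid.index:
            raise ValueError(f"call for {rsid} missing; impute first")
        rec = by_rsid.loc[rsid]
        return int(rec["allele1"] == alt[rsid]) + int(rec["allele2"] == alt[rsid])

    return _diplotype_from_copies(_star_rows(defs, gene), copies_of,
                                  defs.reference_allele(gene))


def star_genotype(gene: str, star: str, calls: pd.DataFrame,
                  defs: Definitions | None = None) -> str:
    """Per-allele genotype label for a single star allele (e.g. ``*1/*2``)."""
    defs = defs or load_definitions()
    row = defs.panel[(defs.panel["gene"] == gene) & (defs.panel["allele"] == star)]
    if row.empty:
        raise ValueError(f"{gene} has no allele {star}")
    row = row.iloc[0]
    sub = _subject_gene_calls(calls, gene).set_index("rsid")
    rec = sub.loc[row["rsid"]]
    n = int(rec["allele1"] == row["alt"]) + int(rec["allele2"] == row["alt"])
    ref = defs.reference_allele(gene)
    ref = "*1" if not ref.startswith("*") else ref
    return {0: f"{ref}/{ref}", 1: _normalize_diplotype(ref, star),
            2: f"{star}/{star}"}[n]


def merge_transporter_haplotype(gene: str, calls: pd.DataFrame,
                                defs: Definitions | None = None,
                                subset_rsids=None) -> str:
    """Merged haplotype rule: 0 variant alleles → wild-type, 1 →
    heterozygous, ≥ 2 → mutant."""
    defs = defs or load_definitions()
    sub = _subject_gene_calls(calls, gene).set_index("rsid")
    panel = defs.panel[(defs.panel["gene"] == gene)
                       & (defs.panel["used_in_phenotype"] == "yes")]
    if subset_rsids is not None:
        panel = panel[panel["rsid"].isin(subset_rsids)]
    total = 0
    for row in panel.itertuples():
        rec = sub.loc[row.rsid]
        total += int(rec["allele1"] == row.alt) + int(rec["allele2"] == row.alt)
    return "wild-type" if total == 0 else ("heterozygous" if total == 1 else "mutant")


# --- phenotype assignment ---------------------------------------------------


_ACTIVITY_CACHE: dict[tuple[int, str], tuple[str, float, dict]] = {}


def _activity_values(gene: str, diplotype: str, defs: Definitions) -> list[float]:
    key = (id(defs), gene)
    if key not in _ACTIVITY_CACHE:
        by_allele = defs.panel[(defs.panel["gene"] == gene)
                               & (defs.panel["activity_value"] != ".")]
        _ACTIVITY_CACHE[key] = (
            defs.reference_allele(gene),
            float(defs.genes.loc[gene, "default_activity"]),
            dict(zip(by_allele["allele"],
                     by_allele["activity_value"].astype(float))))
    ref, default, table = _ACTIVITY_CACHE[key]
    return [default if allele == ref else table[allele]
            for allele in diplotype.split("/")]


def _score_to_phenotype(gene: str, score: float, defs: Definitions) -> str:
    rows = defs.cutpoints[defs.cutpoints["gene"] == gene]
    eps = 1e-9
    for row in rows.itertuples():
        if row.score_min - eps <= score < row.score_max - eps:
            return row.phenotype
    raise ValueError(f"{gene} activity score {score} outside cutpoint table")


def _phenotype_for(gene: str, diplotype: str, defs: Definitions,
                   copy_number: int | None) -> tuple[str, float | None]:
    """Phenotype (and activity score, where applicable) from a diplotype."""
    rule = defs.rule(gene)
    if rule == "diplotype_map":
        try:
            return defs.phenotype_map[(gene, diplotype)], None
        except KeyError:
            raise KeyError(f"no phenotype mapping for {gene} {diplotype}") from None
    if rule == "activity_score":
        score = sum(_activity_values(gene, diplotype, defs))
        if defs.genes.loc[gene, "has_copy_number"] == "yes":
            cn = 2 if copy_number is None else copy_number
            if cn < 0:
                raise ValueError("copy number must be >= 0")
            score = score * cn / 2.0
        return _score_to_phenotype(gene, score, defs), score
    if rule == "genotype_label":
        return diplotype, None
    raise ValueError(f"unknown rule {rule!r} for {gene}")


def assign_phenotype(gene: str, calls: pd.DataFrame,
                     defs: Definitions | None = None,
                     copy_number: int | None = None,
                     subject_id: str = "") -> PhenotypeAssignment:
    """Gene-level phenotype from complete calls for one subject."""
    defs = defs or load_definitions()
    sub = _subject_gene_calls(calls, gene)
    if "imputed" in sub.columns:
        imputed = list(sub.loc[sub["imputed"].astype(bool), "rsid"])
    else:
        imputed = []

    if defs.rule(gene) == "transporter_merge":
        label = merge_transporter_haplotype(gene, calls, defs)
        return PhenotypeAssignment(subject_id, gene, diplotype="-",
                                   phenotype=label, imputed_calls=imputed)

    diplotype, flags = call_diplotype(gene, calls, defs)
    phenotype, score = _phenotype_for(gene, diplotype, defs, copy_number)
    return PhenotypeAssignment(subject_id, gene, diplotype, phenotype,
                               activity_score=score, imputed_calls=imputed,
                               flags=flags)


def _cyp3a5_genotype_label(diplotype: str) -> str:
    """Three-level genotype grouping by functional *1 count.

    *1 is defined by the absence of the loss-of-function alleles on a
    haplotype, so *6-carrying diplotypes group with the corresponding *3
    labels.
    """
    n1 = diplotype.split("/").count("*1")
    return {2: "*1/*1", 1: "*1/*3", 0: "*3/*3"}[n1]


def translate_cohort(genotypes: pd.DataFrame,
                     cyp2d6_cn: pd.Series | None = None,
                     defs: Definitions | None = None,
                     impute: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translate a long genotype table for a whole cohort.

    Returns ``(wide, long)``: a per-subject wide table with the analysis
    columns (one per stratifier plus diplotypes, haplotypes and activity
    scores) and a long table with one row per (subject, gene) assignment.
    """
    defs = defs or load_definitions()
    calls = impute_missing(genotypes, defs) if impute else genotypes

    # vectorised alternate-allele copy matrix (subjects × rsids)
    panel_alt = dict(zip(defs.panel["rsid"], defs.panel["alt"]))
    alt = calls["rsid"].map(panel_alt)
    copy_counts = ((calls["allele1"] == alt).astype(int)
                   + (calls["allele2"] == alt).astype(int))
    mat = (pd.DataFrame({"subject_id": calls["subject_id"],
                         "rsid": calls["rsid"], "copies": copy_counts})
           .pivot(index="subject_id", columns="rsid", values="copies")
           .sort_index())

    imputed_by_subject: dict = {}
    if "imputed" in calls.columns:
        imp = calls[calls["imputed"].astype(bool)]
        for sid, sub in imp.groupby("subject_id"):
            imputed_by_subject[sid] = dict(
                (g, sorted(s["rsid"])) for g, s in sub.groupby("gene"))

    # per-gene static structures
    star_rows = {g: _star_rows(defs, g) for g in defs.genes.index}
    merge_rsids = {
        g: list(defs.panel[(defs.panel["gene"] == g)
                           & (defs.panel["used_in_phenotype"] == "yes")]["rsid"])
        for g in defs.genes.index if defs.rule(g) == "transporter_merge"}
    refs = {g: defs.reference_allele(g) for g in defs.genes.index}
    rules = {g: defs.rule(g) for g in defs.genes.index}
    star_rsid = {(r.gene, r.allele): r.rsid for r in defs.panel.itertuples()}
    _ug = defs.panel.set_index("rsid").loc["rs7439366"]
    ug_ref, ug_alt = _ug["ref"], _ug["alt"]

    def merged_label(total: int) -> str:
        return ("wild-type" if total == 0
                else "heterozygous" if total == 1 else "mutant")

    assignments: list[PhenotypeAssignment] = []
    rows = []
    for subject_id, crow in mat.iterrows():
        cmap = crow.to_dict()
        cn = None
        if cyp2d6_cn is not None and subject_id in cyp2d6_cn.index:
            cn = int(cyp2d6_cn.loc[subject_id])
        imputed_genes = imputed_by_subject.get(subject_id, {})
        per_gene: dict[str, PhenotypeAssignment] = {}
        for gene in defs.genes.index:
            imputed = imputed_genes.get(gene, [])
            if rules[gene] == "transporter_merge":
                total = int(sum(cmap[r] for r in merge_rsids[gene]))
                a = PhenotypeAssignment(subject_id, gene, "-",
                                        merged_label(total),
                                        imputed_calls=imputed)
            else:
                diplotype, flags = _diplotype_from_copies(
                    star_rows[gene], lambda r: int(cmap[r]), refs[gene])
                phenotype, score = _phenotype_for(
                    gene, diplotype, defs,
                    cn if gene == "CYP2D6" else None)
                a = PhenotypeAssignment(subject_id, gene, diplotype,
                                        phenotype, activity_score=score,
                                        imputed_calls=imputed, flags=flags)
            per_gene[gene] = a
            assignments.append(a)

        def star_label(gene: str, star: str) -> str:
            n = int(cmap[star_rsid[(gene, star)]])
            ref = refs[gene]
            return {0: f"{ref}/{ref}", 1: _normalize_diplotype(ref, star),
                    2: f"{star}/{star}"}[n]

        n_ug = int(cmap["rs7439366"])
        ug_alleles = sorted([ug_alt] * n_ug + [ug_ref] * (2 - n_ug),
                            reverse=True)
        rows.append({
            "subject_id": subject_id,
            "slco1b1_diplotype": per_gene["SLCO1B1"].diplotype,
            "slco1b1_phenotype": per_gene["SLCO1B1"].phenotype,
            "cyp3a5_diplotype": per_gene["CYP3A5"].diplotype,
            "cyp3a5_phenotype": per_gene["CYP3A5"].phenotype,
            "cyp3a5_genotype": _cyp3a5_genotype_label(per_gene["CYP3A5"].diplotype),
            "cyp3a5_expresser": "*1" in per_gene["CYP3A5"].diplotype,
            "cyp2d6_phenotype": per_gene["CYP2D6"].phenotype,
            "cyp2d6_score": per_gene["CYP2D6"].activity_score,
            "cyp2c9_phenotype": per_gene["CYP2C9"].phenotype,
            "cyp2c19_phenotype": per_gene["CYP2C19"].phenotype,
            "cyp2b6_phenotype": per_gene["CYP2B6"].phenotype,
            "cyp1a2_phenotype": per_gene["CYP1A2"].phenotype,
            "cyp1a2_score": per_gene["CYP1A2"].activity_score,
            "slc22a1_haplotype": per_gene["SLC22A1"].phenotype,
            "abcb1_haplotype": per_gene["ABCB1"].phenotype,
            "abcb1_core_haplotype": merged_label(
                int(sum(cmap[r] for r in ABCB1_CORE_RSIDS))),
            "slc22a1_star2": star_label("SLC22A1", "*2"),
            "slc22a1_star5": star_label("SLC22A1", "*5"),
            "ugt2b7": per_gene["UGT2B7"].diplotype,
            "ugt2b7_nt": "".join(ug_alleles),
            "imputed_rsids": ";".join(sorted(
                set(sum((a.imputed_calls for a in per_gene.values()), [])))),
        })
    wide = pd.DataFrame(rows).set_index("subject_id")
    long = pd.DataFrame([
        {"subject_id": a.subject_id, "gene": a.gene, "diplotype": a.diplotype,
         "phenotype": a.phenotype, "activity_score": a.activity_score,
         "imputed_rsids": ";".join(a.imputed_calls),
         "flags": ";".join(a.flags)}
        for a in assignments
    ])
    return wide, long
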