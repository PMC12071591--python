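"""Readers and writers for every external format the pipeline touches.

All downstream modules operate on the typed containers defined here:
scoring files (PGS-Catalog-style TSV), sample genotypes/dosages (VCF with
GT and/or DS), sample metadata / kinship / ancestry tables (TSV), and
exome-target regions (BED).  Parsing is strict: malformed rows are either
rejected with row-numbered diagnostics or raise :class:`FormatError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCESTRIES = ("EUR", "AFR", "EAS", "AMR")

#: genes with carrier flags in the metadata table
CARRIER_GENES = (
    "BRCA1", "BRCA2", "TP53", "PALB2", "PTEN", "ATM", "CHEK2", "TP53_R337H",
)

VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file violates its documented format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringVariant:
    """One scoring-file row: a variant and its effect weight.

    ``beta`` is the log-odds contribution per copy of ``effect_allele``.
    """

    variant_id: str
    chrom: str
    pos: int          # 1-based, matching VCF
    effect_allele: str
    other_allele: str
    beta: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(f"effect allele {self.effect_allele!r} is not A/C/G/T")
        if self.other_allele not in VALID_BASES:
            raise ValueError(f"other allele {self.other_allele!r} is not A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele are identical")
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")

    @property
    def key(self) -> tuple[str, int, frozenset]:
        """Position-plus-unordered-allele-pair identity used for matching."""
        return (self.chrom, self.pos, frozenset((self.effect_allele, self.other_allele)))


@dataclass
class ScoringFile:
    """An ordered collection of scoring variants defining one PRS."""

    prs_name: str
    variants: list[ScoringVariant]
    provenance: str = ""
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(v.chrom, v.pos, v.effect_allele, v.other_allele) for v in self.variants]
        if len(set(keys)) != len(keys):
            raise FormatError(f"{self.prs_name}: duplicate (chrom,pos,alleles) rows")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def betas(self) -> np.ndarray:
        return np.array([v.beta for v in self.variants], dtype=float)


@dataclass(frozen=True)
class VariantSite:
    """A biallelic VCF site backing one genotype-matrix column."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Per-sample ALT-allele dosages for an ordered list of sites.

    ``dosages`` is ``n_samples x n_sites`` with values in [0, 2]; missing
    genotypes are stored as NaN and resolved downstream by the score engine.
    """

    samples: list[str]
    sites: list[VariantSite]
    dosages: np.ndarray
    not_found: list[tuple[str, int, frozenset]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bool(np.any(bad)):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class KinshipPair:
    """One estimated relationship, by integer degree or kinship coefficient."""

    sample_a: str
    sample_b: str
    degree: int | None = None
    coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError(f"self-pair for sample {self.sample_a!r}")
        if self.degree is None and self.coefficient is None:
            raise ValueError("pair needs a degree or a kinship coefficient")
        if self.degree is not None and self.degree < 1:
            raise ValueError("relationship degree must be >= 1")
        if self.coefficient is not None and not 0 < self.coefficient <= 0.5:
            raise ValueError("kinship coefficient must lie in (0, 0.5]")


@dataclass
class SampleRecord:
    """Phenotype/covariate/ancestry/carrier metadata for one sample."""

    sample_id: str
    status: str                      # "case" | "control"
    sex: str = "unknown"
    age: float | None = None
    carrier_flags: dict = field(default_factory=dict)
    ancestry_props: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")
        if self.ancestry_props:
            total = sum(self.ancestry_props.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.sample_id}: ancestry proportions sum to {total:.4f}"
                )

    @property
    def is_case(self) -> bool:
        return self.status == "case"


# ---------------------------------------------------------------------------
# scoring files
# ---------------------------------------------------------------------------

#: column mappings per dialect, in ScoringVariant field order
SCORING_DIALECTS = {
    "pgs_catalog": {
        "variant_id": "rsID",
        "chrom": "chr_name",
        "pos": "chr_position",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "effect_weight",
    },
    "harmonized": {
        "variant_id": "hm_rsID",
        "chrom": "hm_chr",
        "pos": "hm_pos",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "effect_weight",
    },
}


def read_scoring_file(path, dialect="pgs_catalog", prs_name=None) -> ScoringFile:
    """Parse a PGS-Catalog-style scoring TSV.

    ``dialect`` is a key of :data:`SCORING_DIALECTS` or an explicit
    field->column mapping.  Rows with non-ACGT alleles or unparseable
    fields are rejected (recorded in ``rejects``, with a warning); a
    missing required column raises :class:`FormatError`.  Zero-beta rows
    are parsed here — filtering is the score engine's job, not the parser's.
    """
    mapping = SCORING_DIALECTS.get(dialect, dialect)
    if not isinstance(mapping, dict):
        raise FormatError(f"unknown scoring dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in mapping.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    cols = {f: df[c].to_numpy() for f, c in mapping.items()}
    variants: list[ScoringVariant] = []
    rejects: list[tuple[int, str]] = []
    for i in range(len(df)):
        row_no = i + 2  # line 1 = header
        rec = {f: cols[f][i] for f in mapping}
        try:
            variants.append(
                ScoringVariant(
                    variant_id=str(rec["variant_id"]),
                    chrom=str(rec["chrom"]),
                    pos=int(rec["pos"]),
                    effect_allele=str(rec["effect_allele"]).upper(),
                    other_allele=str(rec["other_allele"]).upper(),
                    beta=float(rec["beta"]),
                )
            )
        except (TypeError, ValueError) as exc:
            rejects.append((row_no, str(exc)))
    if rejects:
        warnings.warn(
            f"{path}: rejected {len(rejects)} scoring row(s); first: "
            f"line {rejects[0][0]}: {rejects[0][1]}",
            stacklevel=2,
        )
    name = prs_name or str(path)
    return ScoringFile(prs_name=name, variants=variants, rejects=rejects)


def write_scoring_file(scoring: ScoringFile, path, dialect="pgs_catalog") -> None:
    """Write a scoring file back to TSV (field-identical round-trip)."""
    mapping = SCORING_DIALECTS.get(dialect, dialect)
    cols = {mapping["variant_id"]: [v.variant_id for v in scoring.variants],
            mapping["chrom"]: [v.chrom for v in scoring.variants],
            mapping["pos"]: [v.pos for v in scoring.variants],
            mapping["effect_allele"]: [v.effect_allele for v in scoring.variants],
            mapping["other_allele"]: [v.other_allele for v in scoring.variants],
            mapping["beta"]: [repr(v.beta) for v in scoring.variants]}
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(vcf_path, scoring: ScoringFile, prefer_dosage: bool = False) -> GenotypeMatrix:
    """Extract one dosage column per scoring variant found in a VCF.

    Multi-allelic records are split into biallelic alternates; a scoring
    variant matches at most one alternate (by chrom, pos and unordered
    allele pair).  When ``prefer_dosage`` and a DS field is present the
    imputed dosage is used, otherwise hard GT calls give {0, 1, 2} with
    ``./.`` stored as NaN.  Scoring variants absent from the VCF are
    returned in ``not_found``.
    """
    from cyvcf2 import VCF

    lookup = {}
    for i, v in enumerate(scoring.variants):
        lookup.setdefault(v.key, i)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{vcf_path}: VCF contains no samples")

    matched_cols: dict[int, tuple[VariantSite, np.ndarray]] = {}
    for rec in vcf:
        chrom = rec.CHROM
        for alt_idx, alt in enumerate(rec.ALT):
            key = (chrom, rec.POS, frozenset((rec.REF, alt)))
            idx = lookup.get(key)
            if idx is None or idx in matched_cols:
                continue
            col = None
            if prefer_dosage:
                ds = rec.format("DS")
                if ds is not None:
                    ds = np.asarray(ds, dtype=np.float32)
                    col = ds[:, alt_idx] if ds.ndim == 2 else ds
                    col = col.copy()
                    col[~np.isfinite(col)] = np.nan
            if col is None:
                gts = rec.genotype.array()  # (n, ploidy+1); last col = phasing
                alleles = gts[:, :-1]
                missing = np.any(alleles < 0, axis=1)
                col = np.sum(alleles == alt_idx + 1, axis=1).astype(np.float32)
                col[missing] = np.nan
            matched_cols[idx] = (VariantSite(chrom, rec.POS, rec.REF, alt), col)
    vcf.close()

    order = sorted(matched_cols)
    sites = [matched_cols[i][0] for i in order]
    if order:
        dosages = np.column_stack([matched_cols[i][1] for i in order]).astype(np.float32)
    else:
        dosages = np.empty((len(samples), 0), dtype=np.float32)
    with np.errstate(invalid="ignore"):
        dosages = np.clip(dosages, 0.0, 2.0)
    not_found = [v.key for i, v in enumerate(scoring.variants) if i not in matched_cols]
    return GenotypeMatrix(samples=samples, sites=sites, dosages=dosages, not_found=not_found)


def write_vcf(path, samples, sites, dosages, with_ds: bool = False) -> None:
    """Write a minimal VCF 4.2 with GT (and optionally DS) fields.

    Integer dosages map to 0/0, 0/1, 1/1; NaN maps to ``./.``.  Fractional
    dosages require ``with_ds`` (GT is then the rounded hard call).
    """
    dosages = np.asarray(dosages)
    fmt = "GT:DS" if with_ds else "GT"
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_ds:
            fh.write('##FORMAT=<ID=DS,Number=A,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, site in enumerate(sites):
            col = dosages[:, j]
            cells = []
            for d in col:
                if np.isnan(d):
                    cells.append("./." if not with_ds else "./.:.")
                    continue
                gt = gt_map[int(round(min(max(d, 0), 2)))]
                cells.append(f"{gt}:{d:.6g}" if with_ds else gt)
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                     f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# metadata / kinship / ancestry tables
# ---------------------------------------------------------------------------

def read_tables(metadata_path, kinship_path=None, ancestry_path=None):
    """Load and join the sample metadata, kinship and ancestry TSVs.

    Returns ``(records, pairs)``.  Samples without an ancestry row keep an
    empty ``ancestry_props``.  Ancestry rows summing within [0.98, 1.02]
    are renormalized (upstream rounding); rows outside that band are
    rejected with a warning.  Kinship rows referencing unknown samples or
    forming self-pairs are dropped with a warning; duplicate sample ids in
    the metadata raise :class:`FormatError`.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "status"):
        if col not in meta.columns:
            raise FormatError(f"{metadata_path}: missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{metadata_path}: duplicate sample_id(s) {dups[:5]}")

    ancestry: dict[str, dict] = {}
    if ancestry_path is not None:
        anc = pd.read_csv(ancestry_path, sep="\t", dtype={"sample_id": str})
        missing = [c for c in ("sample_id", *ANCESTRIES) if c not in anc.columns]
        if missing:
            raise FormatError(f"{ancestry_path}: missing column(s) {missing}")
        n_bad = 0
        for row in anc.itertuples(index=False):
            props = {k: float(getattr(row, k)) for k in ANCESTRIES}
            total = sum(props.values())
            if not 0.98 <= total <= 1.02:
                n_bad += 1
                continue
            ancestry[row.sample_id] = {k: v / total for k, v in props.items()}
        if n_bad:
            warnings.warn(f"{ancestry_path}: rejected {n_bad} ancestry row(s) "
                          "with proportions summing outside [0.98, 1.02]", stacklevel=2)

    gene_cols = [g for g in CARRIER_GENES if g in meta.columns]
    records = []
    for row in meta.itertuples(index=False):
        age = getattr(row, "age", None)
        records.append(SampleRecord(
            sample_id=row.sample_id,
            status=str(row.status),
            sex=str(getattr(row, "sex", "unknown")),
            age=None if age is None or pd.isna(age) else float(age),
            carrier_flags={g: bool(int(getattr(row, g))) for g in gene_cols},
            ancestry_props=ancestry.get(row.sample_id, {}),
        ))

    pairs: list[KinshipPair] = []
    if kinship_path is not None:
        kin = pd.read_csv(kinship_path, sep="\t",
                          dtype={"sample_a": str, "sample_b": str})
        for col in ("sample_a", "sample_b"):
            if col not in kin.columns:
                raise FormatError(f"{kinship_path}: missing required column {col!r}")
        known = set(meta["sample_id"])
        n_drop = 0
        for row in kin.itertuples(index=False):
            if row.sample_a == row.sample_b:
                n_drop += 1
                continue
            if row.sample_a not in known or row.sample_b not in known:
                n_drop += 1
                continue
            degree = getattr(row, "degree", None)
            coeff = getattr(row, "coefficient", None)
            pairs.append(KinshipPair(
                sample_a=row.sample_a,
                sample_b=row.sample_b,
                degree=None if degree is None or pd.isna(degree) else int(degree),
                coefficient=None if coeff is None or pd.isna(coeff) else float(coeff),
            ))
        if n_drop:
            warnings.warn(f"{kinship_path}: dropped {n_drop} kinship row(s) "
                          "(self-pairs or unknown samples)", stacklevel=2)
    return records, pairs


# ---------------------------------------------------------------------------
# BED targets
# ---------------------------------------------------------------------------

def read_bed(path) -> dict[str, np.ndarray]:
    """Read a 0-based half-open BED into merged, sorted per-chrom intervals.

    Returns ``{chrom: array of shape (k, 2)}`` with columns (start, end).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: BED interval with end <= start")
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        ivals = grp[["start", "end"]].to_numpy()
        ivals = ivals[np.argsort(ivals[:, 0])]
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out
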