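"""Data model and readers/writers for case-control exome cohort tables.

A cohort is exchanged as three tab-separated tables:

sample table
    ``sample_id  cohort  phenotype  ancestry_label  kinship_cluster  icd10_codes``
    with ``cohort`` in {case, control}, ``phenotype`` in
    {crc, polyp, control, unknown} and ``icd10_codes`` semicolon-separated
    (replication mode only; may be empty).
variant table
    ``variant_id  gene  consequence  vest4  af_gnomad  af_ukbb  site_quality
    quality_scheme`` with ``variant_id`` in ``chrom:pos:ref:alt`` (1-based,
    VCF convention), ``vest4`` a missense deleteriousness rank score in
    [0, 1], population allele frequencies in [0, 1] (blank = absent from the
    database), and ``quality_scheme`` in {vqslod, qual}.
call table
    ``sample_id  variant_id  gq  dp  ad_alt  ab  zygosity`` — one genotype
    call per carried variant with genotype quality, depth, alternate-allele
    depth, allele balance and zygosity in {het, hom}.

Everything is held in a :class:`Dataset` of validated pandas DataFrames.
Row-level invariant violations are reported with 1-based data row numbers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consequences import classify_consequence
from .errors import ConfigError, IntegrityError, SchemaError, ValidationError

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample_id", "cohort", "phenotype", "ancestry_label",
                  "kinship_cluster", "icd10_codes"]
VARIANT_COLUMNS = ["variant_id", "gene", "consequence", "vest4", "af_gnomad",
                   "af_ukbb", "site_quality", "quality_scheme"]
CALL_COLUMNS = ["sample_id", "variant_id", "gq", "dp", "ad_alt", "ab",
                "zygosity"]

_VARIANT_ID_RE = re.compile(r"^[^:]+:(\d+):[ACGTN\*\-]+:[ACGTN\*\-]+$",
                            re.IGNORECASE)
_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")

# ICD-10 groups used for replication-mode colorectal phenotype assignment.
PROXIMAL_CODES = frozenset({"C18.0", "C18.2", "C18.3", "C18.4"})
DISTAL_CODES = frozenset({"C18.5", "C18.6", "C18.7", "C19", "C20"})
_COLORECTAL_PREFIXES = ("C18", "C19", "C20")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene role (oncogene / tumor suppressor / unknown) and protein domains.

    ``domains`` is a list of ``(name, start, end)`` with 1-based inclusive
    amino-acid coordinates.
    """
    gene: str
    role: str = "unknown"
    protein_length: int | None = None
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if self.role not in {"oncogene", "tsg", "unknown"}:
            raise ValidationError(f"{self.gene}: unknown role {self.role!r}")
        for name, start, end in self.domains:
            if not 1 <= start <= end:
                raise ValidationError(
                    f"{self.gene}: domain {name} has start {start} > end {end}"
                    if start > end else
                    f"{self.gene}: domain {name} start {start} < 1")
            if self.protein_length is not None and end > self.protein_length:
                raise ValidationError(
                    f"{self.gene}: domain {name} end {end} exceeds protein "
                    f"length {self.protein_length}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one burden analysis.

    Parameters
    ----------
    variant_classes
        Which qualifying classes enter the test: a subset of
        {"missense", "lof"}.
    case_subset
        "crc_only" restricts cases to confirmed carcinomas (polyp cases are
        excluded from the analysis, never recycled as controls);
        "crc_and_polyps" uses the full case cohort.
    threshold_mode
        "variable" scans candidate deleteriousness cutoffs per gene;
        "fixed" evaluates a single cutoff (``fixed_vest_threshold``).
    af_max
        Rare-variant allele-frequency cap applied in both population
        databases (default 1e-4).
    n_permutations
        Label-shuffling iterations for the corrected p value (default 1e7).
    n_genes_tested
        Genome-wide test count used for Bonferroni / borderline thresholds.
    """
    variant_classes: tuple[str, ...] = ("missense", "lof")
    case_subset: str = "crc_and_polyps"
    threshold_mode: str = "variable"
    fixed_vest_threshold: float | None = None
    af_max: float = 1e-4
    n_permutations: int = 10_000_000
    seed: int = 0
    alpha: float = 0.05
    n_genes_tested: int = 18_500

    def __post_init__(self):
        classes = tuple(self.variant_classes)
        object.__setattr__(self, "variant_classes", classes)
        if not set(classes) <= {"missense", "lof"} or not classes:
            raise ConfigError(f"invalid variant_classes {classes!r}")
        if self.case_subset not in {"crc_only", "crc_and_polyps"}:
            raise ConfigError(f"invalid case_subset {self.case_subset!r}")
        if self.threshold_mode not in {"fixed", "variable"}:
            raise ConfigError(f"invalid threshold_mode {self.threshold_mode!r}")
        if (self.threshold_mode == "fixed" and "missense" in classes
                and self.fixed_vest_threshold is None):
            raise ConfigError("fixed threshold_mode with missense requires "
                              "fixed_vest_threshold")
        if not 0 < self.af_max <= 1:
            raise ConfigError("af_max must be in (0, 1]")

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    def label(self) -> str:
        """Human-readable analysis label in the result-table style."""
        cls = {("missense",): "missense",
               ("lof",): "LoF",
               ("missense", "lof"): "LoF and missense",
               ("lof", "missense"): "LoF and missense"}[self.variant_classes]
        sub = {"crc_only": "CRC", "crc_and_polyps": "CRC and polyps"}
        return f"{cls} in {sub[self.case_subset]}"


@dataclass
class Dataset:
    """One cohort (or cohort pair) of samples, variants and genotype calls."""
    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: pd.DataFrame

    @property
    def n_case(self) -> int:
        return int((self.samples["cohort"] == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.samples["cohort"] == "control").sum())

    def subset_cohort(self, cohort: str) -> "Dataset":
        """Restrict to one cohort; variants without surviving calls kept."""
        samples = self.samples[self.samples["cohort"] == cohort]
        calls = self.calls[self.calls["sample_id"].isin(samples["sample_id"])]
        return Dataset(samples.reset_index(drop=True),
                       self.variants.copy(),
                       calls.reset_index(drop=True))

    def copy(self) -> "Dataset":
        return Dataset(self.samples.copy(), self.variants.copy(),
                       self.calls.copy())


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")


def _row_errors(mask: pd.Series, message: str, errors: list[str]) -> None:
    for idx in np.flatnonzero(mask.to_numpy()):
        errors.append(f"row {idx + 1}: {message}")


def _parse_float(series: pd.Series) -> pd.Series:
    """Exact (round-trip safe) string-to-float conversion; bad -> NaN."""
    def conv(v):
        if v is None:
            return np.nan
        if isinstance(v, (int, float, np.floating, np.integer)):
            return float(v)
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan
    return pd.Series([conv(v) for v in series], index=series.index,
                     dtype=float)


def validate_dataset(samples: pd.DataFrame, variants: pd.DataFrame,
                     calls: pd.DataFrame) -> Dataset:
    """Validate the three cohort tables and assemble a :class:`Dataset`.

    Raises :class:`SchemaError` for missing columns, :class:`ValidationError`
    for row-level invariant violations (with 1-based row numbers) and
    :class:`IntegrityError` for dangling cross-table references.
    Adds the derived ``variant_class`` column if absent.
    """
    _require_columns(samples, SAMPLE_COLUMNS[:4], "sample")
    _require_columns(variants, VARIANT_COLUMNS, "variant")
    _require_columns(calls, CALL_COLUMNS, "call")
    samples = samples.copy()
    variants = variants.copy()
    calls = calls.copy()
    for col in ("kinship_cluster", "icd10_codes"):
        if col not in samples.columns:
            samples[col] = ""
    for df, cols in ((samples, ("kinship_cluster", "icd10_codes")),
                     (variants, ())):
        for col in cols:
            df[col] = df[col].fillna("")

    errors: list[str] = []
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    _row_errors(~samples["cohort"].isin(["case", "control"]),
                "cohort must be 'case' or 'control'", errors)
    _row_errors(~samples["phenotype"].isin(["crc", "polyp", "control",
                                            "unknown"]),
                "invalid phenotype", errors)
    _row_errors(samples["phenotype"].isin(["crc", "polyp"])
                & (samples["cohort"] != "case"),
                "phenotype crc/polyp requires cohort 'case'", errors)
    if errors:
        raise ValidationError("sample table:\n" + "\n".join(errors))

    if variants["variant_id"].duplicated().any():
        dup = variants["variant_id"][variants["variant_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate variant_id {dup!r}")
    bad_id = ~variants["variant_id"].astype(str).str.match(_VARIANT_ID_RE)
    _row_errors(bad_id, "variant_id must be chrom:pos:ref:alt with pos >= 1",
                errors)
    for col in ("vest4", "af_gnomad", "af_ukbb"):
        vals = _parse_float(variants[col])
        variants[col] = vals
        _row_errors(vals.notna() & ((vals < 0) | (vals > 1)),
                    f"{col} outside [0, 1]", errors)
    variants["site_quality"] = _parse_float(variants["site_quality"])
    _row_errors(variants["site_quality"].isna(),
                "site_quality must be numeric", errors)
    _row_errors(~variants["quality_scheme"].isin(["vqslod", "qual"]),
                "quality_scheme must be 'vqslod' or 'qual'", errors)
    if errors:
        raise ValidationError("variant table:\n" + "\n".join(errors))
    if "variant_class" not in variants.columns:
        variants["variant_class"] = [classify_consequence(c)
                                     for c in variants["consequence"]]

    for col, lo in (("gq", 0.0), ("dp", 0), ("ad_alt", 0)):
        vals = _parse_float(calls[col])
        calls[col] = vals
        _row_errors(vals.isna() | (vals < lo), f"{col} must be >= {lo}",
                    errors)
    ab = _parse_float(calls["ab"])
    calls["ab"] = ab
    _row_errors(ab.isna() | (ab < 0) | (ab > 1), "ab outside [0, 1]", errors)
    _row_errors(calls["ad_alt"] > calls["dp"], "ad_alt exceeds dp", errors)
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = calls["ad_alt"] / calls["dp"].replace(0, np.nan)
    _row_errors(implied.notna() & ((implied - ab).abs() > 0.05),
                "ab inconsistent with ad_alt/dp", errors)
    _row_errors(~calls["zygosity"].isin(["het", "hom"]),
                "zygosity must be 'het' or 'hom'", errors)
    if errors:
        raise ValidationError("call table:\n" + "\n".join(errors))

    known_samples = set(samples["sample_id"])
    known_variants = set(variants["variant_id"])
    bad_s = ~calls["sample_id"].isin(known_samples)
    bad_v = ~calls["variant_id"].isin(known_variants)
    if bad_s.any() or bad_v.any():
        msgs = []
        for idx in np.flatnonzero(bad_s.to_numpy())[:5]:
            msgs.append(f"row {idx + 1}: unknown sample_id "
                        f"{calls['sample_id'].iloc[idx]!r}")
        for idx in np.flatnonzero(bad_v.to_numpy())[:5]:
            msgs.append(f"row {idx + 1}: unknown variant_id "
                        f"{calls['variant_id'].iloc[idx]!r}")
        raise IntegrityError("call table:\n" + "\n".join(msgs))

    calls = calls.astype({"dp": int, "ad_alt": int, "gq": float, "ab": float})
    return Dataset(samples.reset_index(drop=True),
                   variants.reset_index(drop=True),
                   calls.reset_index(drop=True))


def load_dataset(sample_path: str | Path, variant_path: str | Path,
                 call_path: str | Path) -> Dataset:
    """Read and validate the three cohort TSV tables."""
    frames = []
    for path, name in ((sample_path, "sample"), (variant_path, "variant"),
                       (call_path, "call")):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
        frames.append(pd.read_csv(path, sep="\t", dtype=str,
                                  keep_default_na=False, na_values=[""]))
    samples, variants, calls = frames
    for df in (samples, variants, calls):
        df.replace({np.nan: None})
    return validate_dataset(samples, variants, calls)


_FLOAT_COLS = {"vest4", "af_gnomad", "af_ukbb", "site_quality", "gq", "ab"}


def _format_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in _FLOAT_COLS:
            out[col] = [("" if pd.isna(v) else repr(float(v)))
                        for v in out[col]]
    return out


def write_dataset(d: Dataset, sample_path: str | Path,
                  variant_path: str | Path, call_path: str | Path) -> None:
    """Write the cohort tables as TSV; ``load_dataset`` round-trips them."""
    for df, cols, path in ((d.samples, SAMPLE_COLUMNS, sample_path),
                           (d.variants, VARIANT_COLUMNS, variant_path),
                           (d.calls, CALL_COLUMNS, call_path)):
        cols = [c for c in cols if c in df.columns]
        _format_table(df[cols]).to_csv(path, sep="\t", index=False,
                                       lineterminator="\n")


def load_gene_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV: gene, role, protein_length, domains.

    ``domains`` uses the compact ``name:start-end;name:start-end`` syntax
    with 1-based inclusive coordinates.  Duplicate gene symbols are
    rejected; domain intervals must fit the protein.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, ["gene", "role"], "gene annotation")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate gene {dup!r} in annotation table")
    out: dict[str, GeneAnnotation] = {}
    for i, row in df.iterrows():
        role = row["role"] if pd.notna(row["role"]) else "unknown"
        if role not in {"oncogene", "tsg", "unknown"}:
            raise ValidationError(f"row {i + 1}: invalid role {role!r}")
        length = row.get("protein_length")
        length = int(length) if pd.notna(length) and length != "" else None
        domains = []
        raw = row.get("domains")
        if pd.notna(raw) and raw:
            for part in str(raw).split(";"):
                part = part.strip()
                if not part:
                    continue
                m = re.match(r"^(.+):(\d+)-(\d+)$", part)
                if not m:
                    raise ValidationError(
                        f"row {i + 1}: malformed domain {part!r}")
                domains.append((m.group(1), int(m.group(2)), int(m.group(3))))
        out[row["gene"]] = GeneAnnotation(row["gene"], role, length,
                                          tuple(domains))
    return out


def load_gene_set(path: str | Path) -> list[str]:
    """Read a one-gene-per-line list (blank lines and # comments skipped)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if len(set(genes)) != len(genes):
        raise ValidationError(f"duplicate genes in gene set {path}")
    return genes


def assign_crc_phenotype(icd10_codes: list[str]) -> str:
    """Assign a replication-mode colorectal phenotype from ICD-10 codes.

    Returns ``"proximal"`` (cecum / ascending / transverse colon: C18.0,
    C18.2-C18.4), ``"distal"`` (descending / sigmoid colon, rectosigmoid
    junction, rectum: C18.5-C18.7, C19, C20) or ``"control"`` (no C18-C20
    code).  A sample matching both groups returns ``"ambiguous"`` and a
    sample with a colorectal code outside both groups (e.g. C18.1,
    appendix) returns ``"excluded"``; neither may be used as a case or a
    control.
    """
    proximal = distal = colorectal = False
    for code in icd10_codes:
        code = code.strip()
        if not code:
            continue
        if not _ICD10_RE.match(code):
            raise ValidationError(f"malformed ICD-10 code {code!r}")
        if code in PROXIMAL_CODES:
            proximal = True
        if code in DISTAL_CODES:
            distal = True
        if code.startswith(_COLORECTAL_PREFIXES):
            colorectal = True
    if proximal and distal:
        return "ambiguous"
    if proximal:
        return "proximal"
    if distal:
        return "distal"
    if colorectal:
        return "excluded"
    return "control"


def filter_unrelated_ancestry(d: Dataset, ancestry_label: str = "EUR"
                              ) -> Dataset:
    """Keep one sample per kinship cluster and a single ancestry group.

    Relatedness and ancestry are consumed as precomputed labels
    (``kinship_cluster``, ``ancestry_label``).  Within each non-empty
    kinship cluster the lexicographically smallest ``sample_id`` is
    retained, a deterministic stand-in for "one representative per family".
    """
    s = d.samples
    keep = s["ancestry_label"] == ancestry_label
    s = s[keep]
    clustered = s[s["kinship_cluster"].astype(str) != ""]
    reps = (clustered.sort_values("sample_id")
            .groupby("kinship_cluster", sort=False)["sample_id"].first())
    drop = set(clustered["sample_id"]) - set(reps)
    s = s[~s["sample_id"].isin(drop)]
    calls = d.calls[d.calls["sample_id"].isin(s["sample_id"])]
    log.info("relatedness/ancestry filter: %d -> %d samples",
             len(d.samples), len(s))
    return Dataset(s.reset_index(drop=True), d.variants.copy(),
                   calls.reset_index(drop=True))


def write_config_echo(cfg: AnalysisConfig, path: str | Path) -> None:
    """Echo an analysis configuration as YAML next to the results."""
    data = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
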