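"""Variant and genotype quality control plus cross-cohort calibration.

Case and control exomes sequenced and called on different pipelines carry
different error profiles; a naive burden comparison then measures batch
effects instead of biology.  Two functionally neutral variant classes —
rare synonymous substitutions and in-frame indels — are used as benchmarks:
after filtering, their per-individual rates must match between cohorts
(ratio ~ 1, nonsignificant binomial p).  :func:`calibrate_thresholds`
searches a user-supplied grid of quality / allele-balance cutoffs for the
setting that best equalizes the neutral rates, and
:func:`per_gene_neutral_pvalues` feeds QQ diagnostics of residual per-gene
bias.

Genotype-level thresholds (GQ, depth, alt depth, allele balance) follow the
profile's inequality convention: discovery profiles treat them as minima
(``>=``), the stricter replication profile uses strict ``>``.  Site-level
quality is always a strict cut on the scheme-matched score (VQSLOD or
QUAL), and rarity requires AF <= ``af_max`` in both population databases
(a missing frequency counts as unobserved, i.e. 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort_io import Dataset
from .consequences import classify_consequence  # re-export  # noqa: F401
from .errors import ConfigError
from . import burden as _burden_mod  # late import guard below

log = logging.getLogger(__name__)

NEUTRAL_CLASSES = ("synonymous", "inframe_indel")


@dataclass(frozen=True)
class QCThresholds:
    """One point in QC-filter space.

    ``strict_inequalities`` selects the genotype-level comparison: False
    (discovery) passes values ``>=`` the threshold, True (replication)
    requires strict ``>``.  Site quality always uses strict ``>`` against
    the scheme-matched cutoff.
    """
    min_gq: float = 10.0
    min_ad_alt: int = 2
    min_dp: int = 7
    min_ab: float = 0.1
    min_site_quality_vqslod: float = 2.0
    min_site_quality_qual: float = 38.0
    af_max: float = 1e-4
    strict_inequalities: bool = False

    def __post_init__(self):
        if min(self.min_gq, self.min_ad_alt, self.min_dp, self.min_ab) < 0:
            raise ConfigError("genotype thresholds must be >= 0")
        if not 0 < self.af_max <= 1:
            raise ConfigError("af_max must be in (0, 1]")


def load_qc_profile(name: str) -> QCThresholds:
    """Load a shipped QC profile: discovery_sayo / discovery_spark /
    replication_ukbb."""
    text = resources.files("burdenscan.data").joinpath(
        "qc_profiles.yaml").read_text()
    profiles = yaml.safe_load(text)
    if name not in profiles:
        raise ConfigError(f"unknown QC profile {name!r}; "
                          f"available: {sorted(profiles)}")
    return QCThresholds(**profiles[name])


def pass_genotype_qc(call, t: QCThresholds) -> bool:
    """Does one genotype call pass GQ / alt-depth / depth / allele-balance?"""
    values = (call["gq"], call["ad_alt"], call["dp"], call["ab"])
    cuts = (t.min_gq, t.min_ad_alt, t.min_dp, t.min_ab)
    if t.strict_inequalities:
        return all(v > c for v, c in zip(values, cuts))
    return all(v >= c for v, c in zip(values, cuts))


def pass_site_qc(variant, t: QCThresholds) -> bool:
    """Strict site-quality cut on the scheme-matched score."""
    scheme = variant["quality_scheme"]
    if scheme == "vqslod":
        return variant["site_quality"] > t.min_site_quality_vqslod
    if scheme == "qual":
        return variant["site_quality"] > t.min_site_quality_qual
    raise ConfigError(f"unknown quality scheme {scheme!r}")


def is_rare(variant, af_max: float) -> bool:
    """AF <= af_max in both databases; missing frequency counts as 0."""
    for col in ("af_gnomad", "af_ukbb"):
        af = variant[col]
        if af is not None and not pd.isna(af) and af > af_max:
            return False
    return True


def _genotype_pass_mask(calls: pd.DataFrame, t: QCThresholds) -> np.ndarray:
    if t.strict_inequalities:
        return ((calls["gq"].to_numpy() > t.min_gq)
                & (calls["ad_alt"].to_numpy() > t.min_ad_alt)
                & (calls["dp"].to_numpy() > t.min_dp)
                & (calls["ab"].to_numpy() > t.min_ab))
    return ((calls["gq"].to_numpy() >= t.min_gq)
            & (calls["ad_alt"].to_numpy() >= t.min_ad_alt)
            & (calls["dp"].to_numpy() >= t.min_dp)
            & (calls["ab"].to_numpy() >= t.min_ab))


def _site_pass_mask(variants: pd.DataFrame, t: QCThresholds) -> np.ndarray:
    cut = np.where(variants["quality_scheme"].to_numpy() == "vqslod",
                   t.min_site_quality_vqslod, t.min_site_quality_qual)
    unknown = ~variants["quality_scheme"].isin(["vqslod", "qual"]).to_numpy()
    if unknown.any():
        raise ConfigError("unknown quality scheme in variant table")
    site = variants["site_quality"].to_numpy(dtype=float) > cut
    af_g = variants["af_gnomad"].to_numpy(dtype=float)
    af_u = variants["af_ukbb"].to_numpy(dtype=float)
    rare = ((np.nan_to_num(af_g) <= t.af_max)
            & (np.nan_to_num(af_u) <= t.af_max))
    return site & rare


def apply_qc(d: Dataset, t: QCThresholds) -> Dataset:
    """Filter a dataset to calls passing genotype QC at rare, high-quality
    sites.  Variants left without any surviving call are dropped; per-
    criterion removal counts are logged.  Idempotent."""
    site_ok = _site_pass_mask(d.variants, t)
    ok_variants = set(d.variants.loc[site_ok, "variant_id"])
    geno_ok = _genotype_pass_mask(d.calls, t)
    at_ok_site = d.calls["variant_id"].isin(ok_variants).to_numpy()
    keep = geno_ok & at_ok_site
    log.info("apply_qc: %d/%d variants pass site+rarity, %d/%d calls pass "
             "genotype QC, %d calls retained", site_ok.sum(), len(site_ok),
             geno_ok.sum(), len(geno_ok), keep.sum())
    calls = d.calls[keep]
    surviving = set(calls["variant_id"])
    variants = d.variants[d.variants["variant_id"].isin(surviving)]
    return Dataset(d.samples.copy(), variants.reset_index(drop=True),
                   calls.reset_index(drop=True))


def ratio_test_from_counts(k_case: int, k_control: int, n_case: int,
                           n_control: int) -> tuple[float, float]:
    """Neutral-class rate ratio and two-sided binomial p from totals.

    Under the no-batch-effect null every neutral variant observation lands
    in the case cohort with probability ``n_case / (n_case + n_control)``;
    the p value doubles the smaller binomial tail (capped at 1).  Returns
    ``(ratio, p)`` with ratio = per-individual case rate / control rate
    (NaN when the control rate is 0).
    """
    m = k_case + k_control
    if m == 0:
        return math.nan, 1.0
    pi = n_case / (n_case + n_control)
    upper = stats.binom.sf(k_case - 1, m, pi)
    lower = stats.binom.cdf(k_case, m, pi)
    p = min(1.0, 2.0 * min(upper, lower))
    mean_case = k_case / n_case
    mean_control = k_control / n_control
    ratio = mean_case / mean_control if mean_control > 0 else math.nan
    return ratio, float(p)


def _class_counts(d: Dataset, cls: str) -> int:
    ids = set(d.variants.loc[d.variants["variant_class"] == cls,
                             "variant_id"])
    if not ids:
        return 0
    obs = d.calls[d.calls["variant_id"].isin(ids)]
    return len(obs.drop_duplicates(["sample_id", "variant_id"]))


def neutral_burden_ratio(case_d: Dataset, control_d: Dataset,
                         cls: str) -> tuple[float, float]:
    """Per-individual neutral-class rate ratio (case/control) and its
    two-sided binomial p.  Expects QC to have been applied already; a
    homozygous call counts once (one carried variant)."""
    if cls not in NEUTRAL_CLASSES:
        raise ConfigError(f"{cls!r} is not a neutral benchmark class")
    k_case = _class_counts(case_d, cls)
    k_control = _class_counts(control_d, cls)
    n_case = len(case_d.samples)
    n_control = len(control_d.samples)
    if k_case + k_control == 0:
        log.warning("neutral_burden_ratio: no %s variants survive QC", cls)
    return ratio_test_from_counts(k_case, k_control, n_case, n_control)


@dataclass
class CalibrationReport:
    """Outcome of the cross-cohort threshold search."""
    per_class: dict          # class -> dict(mean_case, mean_control, ratio, p)
    chosen_thresholds: QCThresholds
    feasible: bool           # True if chosen point met p > 0.05 on both classes
    grid_evaluations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variant_class": c, **v} for c, v in self.per_class.items()]
        return pd.DataFrame(rows)


def _evaluate_point(case_d: Dataset, control_d: Dataset,
                    t: QCThresholds) -> dict:
    case_q = apply_qc(case_d, t)
    control_q = apply_qc(control_d, t)
    n_case, n_control = len(case_d.samples), len(control_d.samples)
    out = {}
    for cls in NEUTRAL_CLASSES:
        k_case = _class_counts(case_q, cls)
        k_control = _class_counts(control_q, cls)
        ratio, p = ratio_test_from_counts(k_case, k_control, n_case,
                                          n_control)
        out[cls] = {"mean_case": k_case / n_case,
                    "mean_control": k_control / n_control,
                    "ratio": ratio, "p": p}
    return out


def calibrate_thresholds(case_d: Dataset, control_d: Dataset,
                         grid: list[QCThresholds]) -> CalibrationReport:
    """Grid-search QC thresholds that harmonize neutral variant rates.

    Objective: minimize ``|log(synonymous ratio)|`` subject to two-sided
    p > 0.05 on both neutral classes.  If no grid point is feasible the
    unconstrained minimizer is returned with ``feasible=False``.  Ties are
    broken toward stricter (higher) site-quality cutoffs, then stricter
    allele balance, so the search is deterministic.
    """
    if not grid:
        raise ConfigError("calibration grid is empty")
    records = []
    for i, t in enumerate(grid):
        ev = _evaluate_point(case_d, control_d, t)
        syn, ind = ev["synonymous"], ev["inframe_indel"]
        ratio = syn["ratio"]
        obj = abs(math.log(ratio)) if ratio and ratio > 0 \
            and not math.isnan(ratio) else math.inf
        records.append({
            "grid_index": i, "thresholds": t,
            "ratio_synonymous": ratio, "p_synonymous": syn["p"],
            "ratio_inframe_indel": ind["ratio"],
            "p_inframe_indel": ind["p"],
            "objective": obj,
            "feasible": syn["p"] > 0.05 and ind["p"] > 0.05,
            "per_class": ev,
        })
    trace = pd.DataFrame([{k: v for k, v in r.items() if k != "per_class"}
                          for r in records])

    def sort_key(r):
        t = r["thresholds"]
        return (r["objective"], -t.min_site_quality_vqslod,
                -t.min_site_quality_qual, -t.min_ab, r["grid_index"])

    feasible = [r for r in records if r["feasible"]]
    pool = feasible if feasible else records
    best = min(pool, key=sort_key)
    if not feasible:
        log.warning("calibration: no grid point reached p > 0.05 on both "
                    "neutral classes; returning unconstrained minimizer")
    return CalibrationReport(per_class=best["per_class"],
                             chosen_thresholds=best["thresholds"],
                             feasible=bool(feasible),
                             grid_evaluations=trace)


def per_gene_neutral_pvalues(case_d: Dataset, control_d: Dataset, cls: str,
                             genes: list[str] | None = None
                             ) -> dict[str, float]:
    """One-sided per-gene binomial burden p values on a neutral class.

    These are the inputs to the QQ diagnostic: under no batch effect they
    are (super-)uniform.  ``genes`` defaults to every gene carrying the
    class in either cohort; genes listed explicitly but absent get p = 1.
    """
    if cls not in NEUTRAL_CLASSES:
        raise ConfigError(f"{cls!r} is not a neutral benchmark class")
    n_case, n_control = len(case_d.samples), len(control_d.samples)
    pi_n = (n_case, n_case + n_control)
    counts: dict[str, list[int]] = {}
    for which, d in enumerate((case_d, control_d)):
        v = d.variants[d.variants["variant_class"] == cls]
        obs = d.calls.merge(v[["variant_id", "gene"]], on="variant_id")
        obs = obs.drop_duplicates(["sample_id", "variant_id"])
        for gene, n in obs.groupby("gene").size().items():
            counts.setdefault(gene, [0, 0])[which] = int(n)
    if genes is None:
        genes = sorted(counts)
    out = {}
    for gene in genes:
        k, c = counts.get(gene, (0, 0))
        out[gene] = _burden_mod.binomial_burden_p(k, k + c, *pi_n)
    return out
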