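"""Gene-based rare-variant burden statistics.

The model: after QC, every qualifying variant observation (one carried
variant in one individual) falls in the case cohort with probability
``pi = n_case / (n_case + n_control)`` under the null of no association.
For a gene with ``k`` case observations out of ``m`` total, the one-sided
burden p value is the binomial upper tail ``P(X >= k)``, and enrichment is
summarized by the pooled-rate relative risk

    RR = (k / n_case) / ((k + c) / (n_case + n_control)),

which stays finite even with zero control carriers.

Qualifying variants are loss-of-function (any), and missense with a
deleteriousness rank score (VEST4-style, in [0, 1]) at or above a cutoff.
Because score distributions differ across genes, the cutoff is chosen per
gene by a variable-threshold scan: every observed missense score is a
candidate, and the one minimizing the binomial p wins.  The selection
multiplicity is absorbed by a label-shuffling permutation test that re-runs
the scan in every iteration; the corrected p value is
``(r + 1) / (n_permutations + 1)`` where ``r`` counts permutations whose
(re-optimized) p value is at most the observed one.  Ties between a
permutation and the observed optimum count as exceedances by default
(``tie_policy="inclusive"``), which makes the corrected p a valid p value
and matches the exact hypergeometric null on single-variant-per-carrier
instances; ``tie_policy="strict"`` is available and logs tie counts.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import AnalysisConfig, Dataset, GeneAnnotation
from .errors import ConfigError

log = logging.getLogger(__name__)

__all__ = [
    "BurdenResult", "GeneSetResult", "ScanResult", "analysis_samples",
    "qualifying_counts", "binomial_burden_p", "relative_risk_pooled",
    "variable_threshold_scan", "permutation_corrected_p",
    "exact_permutation_oracle", "geneset_burden",
    "multiple_testing_thresholds", "run_analysis_suite", "replicate_gene",
    "gene_rng",
]


@dataclass
class BurdenResult:
    """Per-gene outcome of one burden analysis configuration."""
    gene: str
    analysis: str
    k: int
    c: int
    n_case: int
    n_control: int
    rate_case: float
    rate_control: float
    rr: float
    vest_threshold: float | None
    p_binomial: float
    p_permutation: float | None = None
    best: bool = False
    flag: str = ""

    @property
    def p(self) -> float:
        return self.p_permutation if self.p_permutation is not None \
            else self.p_binomial

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "variants_per_individual_cases": self.rate_case,
            "variants_per_individual_controls": self.rate_control,
            "relative_risk": self.rr,
            "vest_threshold": self.vest_threshold,
            "p_value": self.p,
            "most_significant_analysis": self.analysis if self.best else "",
            "analysis": self.analysis,
            "case_count": self.k,
            "control_count": self.c,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "p_binomial": self.p_binomial,
            "p_permutation": self.p_permutation,
            "flag": self.flag,
        }


@dataclass
class GeneSetResult:
    """Pooled burden over a gene set under one variant rule."""
    gene_set_name: str
    variant_rule: str
    k: int
    c: int
    n_case: int
    n_control: int
    rate_case: float
    rate_control: float
    rr: float
    p: float
    flag: str = ""


class ScanResult(NamedTuple):
    """Variable-threshold scan outcome (threshold None = LoF-only)."""
    threshold: float | None
    p: float
    k: int
    c: int


def analysis_samples(d: Dataset, cfg: AnalysisConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Case and control sample ids entering an analysis.

    Under ``case_subset="crc_only"`` polyp-only cases are excluded from the
    analysis entirely (never recycled as controls).
    """
    s = d.samples
    if cfg.case_subset == "crc_only":
        cases = s[(s["cohort"] == "case") & (s["phenotype"] == "crc")]
    else:
        cases = s[(s["cohort"] == "case")
                  & s["phenotype"].isin(["crc", "polyp"])]
    controls = s[s["cohort"] == "control"]
    return cases["sample_id"].to_numpy(), controls["sample_id"].to_numpy()


def binomial_burden_p(k: int, m: int, n_case: int, n_total: int) -> float:
    """One-sided upper-tail burden p: P(X >= k), X ~ Binomial(m, n_case/n_total)."""
    if not 0 <= k <= m:
        raise ConfigError(f"invalid counts k={k}, m={m}")
    if not 0 < n_case < n_total:
        raise ConfigError(f"invalid cohort sizes n_case={n_case}, "
                          f"n_total={n_total}")
    if m == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, m, n_case / n_total))


def relative_risk_pooled(k: int, n_case: int, c: int, n_control: int
                         ) -> float:
    """Pooled-rate relative risk: case rate over the combined-cohort rate.

    Finite whenever ``k + c > 0`` (zero control carriers allowed); raises
    when there are no observations at all.
    """
    if k + c <= 0:
        raise ConfigError("relative risk undefined with k + c = 0")
    return (k / n_case) / ((k + c) / (n_case + n_control))


def exact_permutation_oracle(K: int, k_obs: int, n_case: int,
                             n_total: int) -> float:
    """Closed-form permutation null for single-variant-per-carrier genes.

    When each of ``K`` carriers carries exactly one qualifying variant and
    the statistic is monotone in the case-carrier count, shuffling labels
    makes that count Hypergeometric(N=n_total, K, n=n_case); returns
    ``P(X >= k_obs)``.
    """
    if not (0 <= k_obs <= K <= n_total and 0 < n_case <= n_total):
        raise ConfigError("invalid hypergeometric oracle arguments")
    return float(stats.hypergeom.sf(k_obs - 1, n_total, K, n_case))


def multiple_testing_thresholds(alpha: float, n_genes_tested: int
                                ) -> tuple[float, float]:
    """(Bonferroni, borderline) genome-wide thresholds.

    Bonferroni = alpha / n_genes; borderline = 1 / n_genes (the level at
    which one false positive is expected across the scan).
    """
    if not 0 < alpha < 1 or n_genes_tested < 1:
        raise ConfigError("need alpha in (0,1) and n_genes_tested >= 1")
    return alpha / n_genes_tested, 1.0 / n_genes_tested


# ---------------------------------------------------------------------------
# internal per-gene engine

def _gene_observations(d: Dataset, gene: str, cfg: AnalysisConfig
                       ) -> pd.DataFrame:
    """Qualifying-eligible observations for a gene: one row per
    (sample, variant) with ``is_lof`` and ``vest`` columns."""
    v = d.variants[d.variants["gene"] == gene]
    keep = pd.Series(False, index=v.index)
    if "lof" in cfg.variant_classes:
        keep |= v["variant_class"] == "lof"
    if "missense" in cfg.variant_classes:
        is_mis = v["variant_class"] == "missense"
        scoreless = is_mis & v["vest4"].isna()
        if scoreless.any():
            log.info("gene %s: %d missense variants lack a deleteriousness "
                     "score and can never qualify", gene, scoreless.sum())
        keep |= is_mis & v["vest4"].notna()
    v = v[keep]
    if v.empty:
        return pd.DataFrame(columns=["sample_id", "variant_id", "is_lof",
                                     "vest"])
    obs = d.calls.merge(
        v[["variant_id", "variant_class", "vest4"]], on="variant_id")
    obs = obs.drop_duplicates(["sample_id", "variant_id"])
    obs["is_lof"] = obs["variant_class"] == "lof"
    obs = obs.rename(columns={"vest4": "vest"})
    return obs[["sample_id", "variant_id", "is_lof", "vest"]]


class _GeneEngine:
    """Precomputed threshold/count tables for one gene and one config.

    ``W`` is the carriers x thresholds matrix of per-carrier qualifying
    observation counts; column totals ``m_j`` are label-invariant, so a
    permutation only changes the case totals ``k_j = sum over shuffled-case
    carriers of W``.  Binomial tail lookups are tabulated once per column.
    """

    def __init__(self, d: Dataset, gene: str, cfg: AnalysisConfig):
        case_ids, control_ids = analysis_samples(d, cfg)
        self.n_case = len(case_ids)
        self.n_control = len(control_ids)
        self.n_total = self.n_case + self.n_control
        if not 0 < self.n_case < self.n_total:
            raise ConfigError("analysis needs at least one case and one "
                              "control sample")
        analysis_ids = set(case_ids) | set(control_ids)
        obs = _gene_observations(d, gene, cfg)
        obs = obs[obs["sample_id"].isin(analysis_ids)]

        self.has_missense_scan = False
        if "missense" in cfg.variant_classes:
            if cfg.threshold_mode == "variable":
                vests = np.unique(obs["vest"].dropna().to_numpy())
                if vests.size:
                    # ascending; the +inf sentinel is the "no missense
                    # qualifies" cutoff, needed so the scan dominates every
                    # fixed threshold when LoF observations are in the mix
                    self.thresholds = list(vests)
                    if "lof" in cfg.variant_classes:
                        self.thresholds.append(math.inf)
                    self.has_missense_scan = True
                else:
                    self.thresholds = [None]
            else:
                self.thresholds = [float(cfg.fixed_vest_threshold)]
        else:
            self.thresholds = [None]

        carriers, codes = np.unique(obs["sample_id"].to_numpy(),
                                    return_inverse=True)
        self.carriers = carriers
        S, J = len(carriers), len(self.thresholds)
        W = np.zeros((S, J), dtype=np.int64)
        is_lof = obs["is_lof"].to_numpy(dtype=bool)
        vest = obs["vest"].to_numpy(dtype=float)
        for j, t in enumerate(self.thresholds):
            if "missense" in cfg.variant_classes and t is not None:
                qual = is_lof | (~np.isnan(vest) & (vest >= t))
            else:
                qual = is_lof
            if qual.any():
                W[:, j] = np.bincount(codes[qual], minlength=S)
        self.W = W
        self.m = W.sum(axis=0)
        pi = self.n_case / self.n_total
        # p_of_k[j][k] = P(X >= k | m_j, pi) for k = 0..m_j
        self.p_of_k = [stats.binom.sf(np.arange(mj + 1) - 1, mj, pi)
                       if mj > 0 else np.array([1.0])
                       for mj in self.m]
        case_set = set(case_ids)
        self.case_mask = np.fromiter((s in case_set for s in carriers),
                                     dtype=bool, count=S)

    def observed(self) -> ScanResult:
        k = self.W[self.case_mask].sum(axis=0) if self.case_mask.any() \
            else np.zeros_like(self.m)
        p = np.array([self.p_of_k[j][k[j]] for j in range(len(self.m))])
        j = int(np.argmin(p))  # thresholds ascending: ties -> most inclusive
        return ScanResult(self.thresholds[j], float(p[j]), int(k[j]),
                          int(self.m[j] - k[j]))

    def permutation_p(self, rng: np.random.Generator, n_permutations: int,
                      tie_policy: str = "inclusive",
                      early_exit_r: int | None = 1000,
                      batch_size: int = 200_000,
                      ) -> tuple[float, int, int, int]:
        """Corrected p = (r + 1)/(n + 1); returns (p, r, n_done, ties)."""
        if n_permutations <= 0:
            raise ConfigError("n_permutations must be positive")
        if tie_policy not in {"inclusive", "strict"}:
            raise ConfigError(f"unknown tie_policy {tie_policy!r}")
        S = len(self.carriers)
        p_obs = self.observed().p
        if S == 0 or p_obs >= 1.0:
            # every permutation does at least as well; p = 1 exactly
            return 1.0, n_permutations, n_permutations, n_permutations
        J = len(self.m)
        r = ties = n_done = 0
        while n_done < n_permutations:
            b = min(batch_size, n_permutations - n_done)
            ind = _case_indicators(rng, b, S, self.n_case, self.n_total)
            K = ind @ self.W  # (b, J) case totals per threshold
            p_min = np.full(b, np.inf)
            for j in range(J):
                np.minimum(p_min, self.p_of_k[j][K[:, j]], out=p_min)
            ties += int((p_min == p_obs).sum())
            if tie_policy == "inclusive":
                r += int((p_min <= p_obs).sum())
            else:
                r += int((p_min < p_obs).sum())
            n_done += b
            if early_exit_r is not None and r >= early_exit_r:
                break
        if ties:
            log.info("permutation: %d/%d iterations tied the observed "
                     "optimum (policy=%s)", ties, n_done, tie_policy)
        return (r + 1) / (n_done + 1), r, n_done, ties


def _case_indicators(rng: np.random.Generator, n_batch: int, S: int,
                     n_case: int, n_total: int) -> np.ndarray:
    """Case-label indicators for S carriers under a full label shuffle.

    Sequentially draws without replacement from a pool of n_case case and
    n_total - n_case control labels (vectorized across permutations).
    """
    rem_case = np.full(n_batch, n_case, dtype=np.int64)
    out = np.empty((n_batch, S), dtype=np.int64)
    for i in range(S):
        p = rem_case / (n_total - i)
        b = rng.random(n_batch) < p
        out[:, i] = b
        rem_case -= b
    return out


def gene_rng(seed: int, gene: str) -> np.random.Generator:
    """Per-gene random stream, independent of gene processing order.

    The master seed is combined with a CRC32 of the gene symbol through a
    SeedSequence spawn key, so adding or dropping genes never perturbs
    another gene's permutations.
    """
    key = zlib.crc32(gene.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=(key,)))


# ---------------------------------------------------------------------------
# public per-gene operations

def qualifying_counts(d: Dataset, gene: str, cfg: AnalysisConfig,
                      vest_threshold: float | None
                      ) -> tuple[int, int, list[str]]:
    """Case/control qualifying observation counts at one fixed threshold.

    A LoF observation qualifies iff "lof" is among the configured classes;
    a missense observation qualifies iff "missense" is configured and its
    score is >= ``vest_threshold``.  One observation per (sample, variant)
    regardless of zygosity.  Returns ``(k, c, carrier_sample_ids)``.
    """
    case_ids, control_ids = analysis_samples(d, cfg)
    obs = _gene_observations(d, gene, cfg)
    analysis_ids = set(case_ids) | set(control_ids)
    obs = obs[obs["sample_id"].isin(analysis_ids)]
    qual = obs["is_lof"].to_numpy(dtype=bool)
    if "missense" in cfg.variant_classes and vest_threshold is not None:
        vest = obs["vest"].to_numpy(dtype=float)
        qual = qual | (~np.isnan(vest) & (vest >= vest_threshold))
    obs = obs[qual]
    case_set = set(case_ids)
    in_case = obs["sample_id"].isin(case_set)
    k = int(in_case.sum())
    c = int(len(obs) - k)
    carriers = sorted(obs["sample_id"].unique())
    return k, c, carriers


def variable_threshold_scan(d: Dataset, gene: str,
                            cfg: AnalysisConfig) -> ScanResult:
    """Scan candidate deleteriousness cutoffs and minimize the binomial p.

    Candidates are the observed missense scores for the gene (cases and
    controls pooled); LoF observations qualify at every cutoff.  Ties on
    the minimum p go to the smallest (most inclusive) cutoff.  With no
    missense observations the scan degenerates to the LoF-only evaluation
    with threshold ``None``.
    """
    engine = _GeneEngine(d, gene, cfg.replace(threshold_mode="variable"))
    return engine.observed()


def permutation_corrected_p(d: Dataset, gene: str, cfg: AnalysisConfig,
                            tie_policy: str = "inclusive",
                            rescan: bool = True,
                            early_exit_r: int | None = 1000,
                            rng: np.random.Generator | None = None,
                            return_details: bool = False):
    """Label-shuffling correction of the per-gene burden p value.

    Shuffles case/control status across all analysis samples (the carrier
    structure and scores stay fixed), recomputes the same statistic
    pipeline per iteration — re-running the threshold scan when
    ``cfg.threshold_mode == "variable"`` and ``rescan`` is True — and
    returns ``(r + 1) / (n + 1)`` where ``r`` counts permutations whose p
    value beats (or, under the default inclusive policy, ties) the
    observed one.  ``early_exit_r`` stops once the estimate is precise
    enough for clearly null genes (relative error < ~7% at r = 1000).
    """
    if cfg.n_permutations <= 0:
        raise ConfigError("n_permutations must be positive")
    run_cfg = cfg
    if cfg.threshold_mode == "variable" and not rescan:
        observed = variable_threshold_scan(d, gene, cfg)
        run_cfg = cfg.replace(threshold_mode="fixed",
                              fixed_vest_threshold=observed.threshold
                              if observed.threshold is not None else None)
        if run_cfg.fixed_vest_threshold is None:
            run_cfg = run_cfg.replace(
                variant_classes=tuple(c for c in cfg.variant_classes
                                      if c != "missense") or ("lof",))
    engine = _GeneEngine(d, gene, run_cfg)
    if rng is None:
        rng = gene_rng(cfg.seed, gene)
    p, r, n_done, ties = engine.permutation_p(
        rng, cfg.n_permutations, tie_policy=tie_policy,
        early_exit_r=early_exit_r)
    if return_details:
        return p, r, n_done, ties
    return p


def _result_for(d: Dataset, gene: str, cfg: AnalysisConfig,
                permute: bool = True, tie_policy: str = "inclusive",
                early_exit_r: int | None = 1000) -> BurdenResult:
    engine = _GeneEngine(d, gene, cfg)
    scan = engine.observed()
    k, c = scan.k, scan.c
    n_case, n_control = engine.n_case, engine.n_control
    flag = ""
    if k + c > 0:
        rr = relative_risk_pooled(k, n_case, c, n_control)
    else:
        rr = math.nan
        flag = "no_qualifying_variants"
    p_perm = None
    if permute and k + c > 0:
        p_perm, _, _, _ = engine.permutation_p(
            gene_rng(cfg.seed, gene), cfg.n_permutations,
            tie_policy=tie_policy, early_exit_r=early_exit_r)
    elif permute:
        p_perm = 1.0
    return BurdenResult(
        gene=gene, analysis=cfg.label(), k=k, c=c,
        n_case=n_case, n_control=n_control,
        rate_case=k / n_case, rate_control=c / n_control,
        rr=rr, vest_threshold=scan.threshold,
        p_binomial=scan.p, p_permutation=p_perm, flag=flag)


_SUITE_CLASSES = (("missense",), ("lof",), ("missense", "lof"))
_SUITE_SUBSETS = ("crc_only", "crc_and_polyps")


def run_analysis_suite(d: Dataset, cfg_base: AnalysisConfig,
                       genes: Iterable[str] | None = None,
                       permute: bool = True,
                       tie_policy: str = "inclusive",
                       early_exit_r: int | None = 1000
                       ) -> list[BurdenResult]:
    """Run the six standard analyses per gene.

    Three qualifying-class groups (missense only / LoF only / combined)
    crossed with two case subsets (confirmed carcinomas only / carcinomas
    plus significant polyps).  Per gene, the single most significant
    analysis is flagged ``best``.  Results are deterministic and invariant
    to gene processing order.
    """
    if genes is None:
        eligible = d.variants["variant_class"].isin(["missense", "lof"])
        genes = sorted(d.variants.loc[eligible, "gene"].unique())
    results: list[BurdenResult] = []
    for gene in genes:
        per_gene = []
        for subset in _SUITE_SUBSETS:
            for classes in _SUITE_CLASSES:
                cfg = cfg_base.replace(variant_classes=classes,
                                       case_subset=subset,
                                       threshold_mode="variable")
                per_gene.append(_result_for(d, gene, cfg, permute=permute,
                                            tie_policy=tie_policy,
                                            early_exit_r=early_exit_r))
        best = min(per_gene, key=lambda r: (r.p, r.analysis))
        best.best = True
        results.extend(per_gene)
    return results


def geneset_burden(d: Dataset, genes: list[str],
                   roles: dict[str, GeneAnnotation], rule: str,
                   cfg: AnalysisConfig,
                   gene_set_name: str = "gene_set") -> GeneSetResult:
    """Pooled qualifying-variant burden across a gene set.

    Rules: ``"lof"`` counts LoF observations, skipping genes annotated as
    oncogenes (loss of an oncogene is presumed protective);
    ``"missense_vest_ge_0.5"`` counts missense observations with score
    >= 0.5; ``"combined"`` is the union of the two observation sets (no
    double counting).  Reports per-individual rates, pooled-rate RR and
    the one-sided binomial p.
    """
    if not genes:
        raise ConfigError("empty gene set")
    missing = [g for g in genes if g not in roles]
    if missing:
        raise ConfigError(f"missing role annotation for genes: {missing[:5]}")
    if rule not in {"lof", "missense_vest_ge_0.5", "combined"}:
        raise ConfigError(f"unknown variant rule {rule!r}")

    case_ids, control_ids = analysis_samples(d, cfg)
    n_case, n_control = len(case_ids), len(control_ids)
    v = d.variants[d.variants["gene"].isin(genes)]
    oncogenes = {g for g in genes if roles[g].role == "oncogene"}
    lof_ok = (v["variant_class"] == "lof") & ~v["gene"].isin(oncogenes)
    mis_ok = (v["variant_class"] == "missense") & (v["vest4"] >= 0.5)
    if rule == "lof":
        mask = lof_ok
    elif rule == "missense_vest_ge_0.5":
        mask = mis_ok
    else:
        mask = lof_ok | mis_ok
    ids = set(v.loc[mask, "variant_id"])
    obs = d.calls[d.calls["variant_id"].isin(ids)]
    obs = obs.drop_duplicates(["sample_id", "variant_id"])
    obs = obs[obs["sample_id"].isin(set(case_ids) | set(control_ids))]
    in_case = obs["sample_id"].isin(set(case_ids))
    k, c = int(in_case.sum()), int(len(obs) - in_case.sum())
    flag = ""
    if k + c > 0:
        rr = relative_risk_pooled(k, n_case, c, n_control)
        p = binomial_burden_p(k, k + c, n_case, n_case + n_control)
    else:
        rr, p, flag = math.nan, 1.0, "no_qualifying_variants"
    return GeneSetResult(gene_set_name, rule, k, c, n_case, n_control,
                         k / n_case, c / n_control, rr, p, flag)


def replicate_gene(d: Dataset, gene: str, fixed_t: float | None,
                   cfg: AnalysisConfig, permute: bool = False,
                   tie_policy: str = "inclusive",
                   early_exit_r: int | None = 1000
                   ) -> tuple[BurdenResult, BurdenResult]:
    """Replication-mode evaluation: discovery threshold, then a fresh scan.

    Returns ``(fixed, rescanned)`` burden results: the first applies the
    discovery cohort's chosen cutoff unchanged to the replication data,
    the second re-runs the variable-threshold scan to measure the maximal
    signal.  A gene absent from the replication data yields two flagged
    p = 1 results.
    """
    if fixed_t is not None:
        fixed_cfg = cfg.replace(threshold_mode="fixed",
                                fixed_vest_threshold=fixed_t)
    else:
        fixed_cfg = cfg.replace(
            threshold_mode="fixed", fixed_vest_threshold=None,
            variant_classes=tuple(x for x in cfg.variant_classes
                                  if x != "missense") or ("lof",))
    fixed = _result_for(d, gene, fixed_cfg, permute=permute,
                        tie_policy=tie_policy, early_exit_r=early_exit_r)
    rescanned = _result_for(d, gene, cfg.replace(threshold_mode="variable"),
                            permute=permute, tie_policy=tie_policy,
                            early_exit_r=early_exit_r)
    if gene not in set(d.variants["gene"]):
        fixed.flag = rescanned.flag = "gene_absent"
    return fixed, rescanned
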