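"""Synthetic case-control exome cohorts with known ground truth.

The generator emulates the statistical structure the burden analysis
assumes, at parameters matching the study design it supports:

* per-individual neutral variant counts are Poisson — synonymous at ~26.5
  per individual, in-frame indels around 0.5 — with each observation a
  private rare variant assigned to a uniformly chosen gene;
* "planted" risk genes carry one deleterious variant per carrier, carriers
  drawn per individual at cohort-specific rates (e.g. 0.019 in cases vs
  ~2e-4 in controls for a strong signal), LoF with a configurable fraction
  and missense otherwise with a Beta-distributed deleteriousness score;
* unplanted genes receive background deleterious variants at equal
  case/control rates (null genes);
* the two cohorts use different site-quality schemes (VQSLOD-like for
  cases, QUAL-like for controls) and an optional batch shift moves one
  cohort's site-quality / allele-balance distributions, emulating the
  cross-platform technical bias the calibration step must absorb;
* a configurable fraction of genotype calls is sabotaged to fail exactly
  one genotype-QC criterion, so per-criterion filter counts are testable.

Every draw comes from a named substream of the master seed (samples,
neutral, deleterious, qc), so adding a stage never perturbs another
stage's randomness and identical seeds give byte-identical tables.  A
:class:`TruthTable` records every deleterious observation and the intended
QC fate of every call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_io import Dataset, AnalysisConfig, validate_dataset
from .errors import ConfigError
from . import burden as _burden

_STREAMS = {"samples": 0, "neutral": 1, "deleterious": 2, "qc": 3,
            "replicates": 4}

# reference discovery-profile cuts used for ground-truth QC bookkeeping
_REF = {"gq": 10.0, "ad_alt": 2, "dp": 7, "ab": 0.1,
        "vqslod": 2.0, "qual": 38.0}


@dataclass(frozen=True)
class PlantedGene:
    """A risk gene with cohort-specific carrier rates."""
    gene: str
    case_carrier_rate: float
    control_carrier_rate: float
    lof_fraction: float = 0.5
    vest_alpha: float = 2.0
    vest_beta: float = 2.0

    def __post_init__(self):
        if not (0 <= self.case_carrier_rate <= 1
                and 0 <= self.control_carrier_rate <= 1):
            raise ConfigError(f"{self.gene}: carrier rates must be in [0,1]")
        if not 0 <= self.lof_fraction <= 1:
            raise ConfigError(f"{self.gene}: lof_fraction must be in [0,1]")


@dataclass(frozen=True)
class SimulationParams:
    """Generative model for one synthetic cohort pair.

    Defaults mirror the discovery-study conditions: 212 cases vs 31,699
    controls, ~26.5 rare synonymous variants per individual, a small
    in-frame indel rate, and a per-gene background deleterious rate of
    0.01 per individual (a realistic rare qualifying-variant rate for a
    sizeable gene).  ``n_genes`` defaults to a test-scale gene universe.
    """
    n_case: int = 212
    n_control: int = 31_699
    n_genes: int = 50
    synonymous_rate: float = 26.5
    inframe_rate: float = 0.5
    background_deleterious_rate: float = 0.01
    background_lof_fraction: float = 0.1
    planted_genes: tuple[PlantedGene, ...] = ()
    batch_site_quality_delta: float = 0.0
    batch_ab_delta: float = 0.0
    batch_shift_cohort: str = "control"
    qc_fail_fraction: float = 0.05
    crc_fraction: float = 174 / 212
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_genes",
                           tuple(self.planted_genes))
        for rate in (self.synonymous_rate, self.inframe_rate,
                     self.background_deleterious_rate):
            if rate < 0:
                raise ConfigError("rates must be >= 0")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ConfigError("qc_fail_fraction must be in [0,1]")
        if self.batch_shift_cohort not in {"case", "control"}:
            raise ConfigError("batch_shift_cohort must be case or control")

    def replace(self, **kw) -> "SimulationParams":
        return replace(self, **kw)

    def gene_universe(self) -> list[str]:
        background = [f"G{i:04d}" for i in range(1, self.n_genes + 1)]
        planted = [pg.gene for pg in self.planted_genes]
        return planted + [g for g in background if g not in planted]


@dataclass
class TruthTable:
    """Generator bookkeeping: what was planted and what QC should keep."""
    carriers: pd.DataFrame   # sample_id, gene, variant_id, class, vest4, planted
    call_qc: pd.DataFrame    # sample_id, variant_id, failed_criterion, expected_pass
    planted: pd.DataFrame    # gene, case_carrier_rate, control_carrier_rate


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _spawn_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS["replicates"],
                                                 index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


class _CohortBuilder:
    """Accumulates variant and call rows with unique positions."""

    def __init__(self):
        self.pos = 0
        self.v_rows: list[dict] = []
        self.c_rows: list[dict] = []

    def add(self, sample_id: str, gene: str, consequence: str,
            vest4: float | None, scheme: str, site_quality: float) -> str:
        self.pos += 1
        ref, alt = ("A", "AGT") if consequence == "inframe_insertion" \
            else ("A", "G")
        vid = f"chr1:{self.pos}:{ref}:{alt}"
        self.v_rows.append({
            "variant_id": vid, "gene": gene, "consequence": consequence,
            "vest4": vest4, "af_gnomad": 0.0, "af_ukbb": 0.0,
            "site_quality": site_quality, "quality_scheme": scheme})
        self.c_rows.append({"sample_id": sample_id, "variant_id": vid})
        return vid


def _site_quality(rng, scheme: str, n: int) -> np.ndarray:
    if scheme == "vqslod":
        return rng.normal(10.0, 4.0, n)
    return rng.normal(200.0, 60.0, n)


def simulate_cohort(p: SimulationParams) -> tuple[Dataset, TruthTable]:
    """Draw one case-control cohort pair plus its ground-truth table."""
    rng_s = _rng(p.seed, "samples")
    rng_n = _rng(p.seed, "neutral")
    rng_d = _rng(p.seed, "deleterious")
    rng_q = _rng(p.seed, "qc")

    case_ids = [f"case_{i:05d}" for i in range(1, p.n_case + 1)]
    control_ids = [f"control_{i:05d}" for i in range(1, p.n_control + 1)]
    is_crc = rng_s.random(p.n_case) < p.crc_fraction
    samples = pd.DataFrame({
        "sample_id": case_ids + control_ids,
        "cohort": ["case"] * p.n_case + ["control"] * p.n_control,
        "phenotype": [("crc" if f else "polyp") for f in is_crc]
        + ["control"] * p.n_control,
        "ancestry_label": "EUR",
        "kinship_cluster": "",
        "icd10_codes": "",
    })

    universe = np.array(p.gene_universe())
    builder = _CohortBuilder()
    truth_carriers: list[dict] = []

    # --- neutral classes -------------------------------------------------
    for cohort_ids, scheme in ((case_ids, "vqslod"), (control_ids, "qual")):
        for cls_rate, consequence in ((p.synonymous_rate,
                                       "synonymous_variant"),
                                      (p.inframe_rate, "inframe_insertion")):
            if cls_rate == 0:
                continue
            counts = rng_n.poisson(cls_rate, len(cohort_ids))
            owners = np.repeat(np.asarray(cohort_ids), counts)
            total = len(owners)
            genes = universe[rng_n.integers(0, len(universe), total)]
            quals = _site_quality(rng_n, scheme, total)
            for sid, gene, q in zip(owners, genes, quals):
                builder.add(sid, gene, consequence, None, scheme, float(q))

    # --- deleterious variants --------------------------------------------
    def plant(gene: str, ids: list[str], rate: float, lof_frac: float,
              vest_draw, scheme: str, planted: bool):
        if rate == 0 or not ids:
            return
        hits = np.flatnonzero(rng_d.random(len(ids)) < rate)
        for idx in hits:
            sid = ids[idx]
            lof = rng_d.random() < lof_frac
            vest = None if lof else float(vest_draw())
            consequence = "stop_gained" if lof else "missense_variant"
            q = float(_site_quality(rng_d, scheme, 1)[0])
            vid = builder.add(sid, gene, consequence, vest, scheme, q)
            truth_carriers.append({
                "sample_id": sid, "gene": gene, "variant_id": vid,
                "variant_class": "lof" if lof else "missense",
                "vest4": vest, "planted": planted})

    planted_names = set()
    for pg in p.planted_genes:
        planted_names.add(pg.gene)
        draw = lambda a=pg.vest_alpha, b=pg.vest_beta: rng_d.beta(a, b)
        plant(pg.gene, case_ids, pg.case_carrier_rate, pg.lof_fraction,
              draw, "vqslod", True)
        plant(pg.gene, control_ids, pg.control_carrier_rate,
              pg.lof_fraction, draw, "qual", True)
    uniform = lambda: rng_d.random()
    for gene in universe:
        if gene in planted_names:
            continue
        plant(gene, case_ids, p.background_deleterious_rate,
              p.background_lof_fraction, uniform, "vqslod", False)
        plant(gene, control_ids, p.background_deleterious_rate,
              p.background_lof_fraction, uniform, "qual", False)

    variants = pd.DataFrame(
        builder.v_rows, columns=["variant_id", "gene", "consequence",
                                 "vest4", "af_gnomad", "af_ukbb",
                                 "site_quality", "quality_scheme"])
    calls = pd.DataFrame(builder.c_rows,
                         columns=["sample_id", "variant_id"])

    # --- batch shift on the designated cohort -----------------------------
    shifted = calls["sample_id"].str.startswith(p.batch_shift_cohort)
    if p.batch_site_quality_delta:
        vid_shift = set(calls.loc[shifted, "variant_id"])
        mask = variants["variant_id"].isin(vid_shift)
        variants.loc[mask, "site_quality"] += p.batch_site_quality_delta

    # --- genotype-level fields --------------------------------------------
    n_calls = len(calls)
    gq = rng_q.uniform(30, 90, n_calls)
    dp = rng_q.integers(20, 61, n_calls)
    ab = rng_q.uniform(0.35, 0.65, n_calls)
    if p.batch_ab_delta:
        ab = np.where(shifted.to_numpy(),
                      np.clip(ab + p.batch_ab_delta, 0.02, 0.98), ab)
    ad = np.maximum(np.rint(ab * dp).astype(int), 1)
    failed = np.array([""] * n_calls, dtype=object)
    if p.qc_fail_fraction > 0 and n_calls:
        n_fail = int(round(p.qc_fail_fraction * n_calls))
        which = rng_q.choice(n_calls, size=n_fail, replace=False)
        crit = rng_q.integers(0, 4, n_fail)
        for idx, cr in zip(which, crit):
            if cr == 0:                       # gq below minimum
                gq[idx], failed[idx] = 5.0, "gq"
            elif cr == 1:                     # alt depth below minimum
                dp[idx], ad[idx], failed[idx] = 8, 1, "ad_alt"
            elif cr == 2:                     # depth below minimum
                dp[idx], ad[idx], failed[idx] = 5, 3, "dp"
            else:                             # allele balance below minimum
                dp[idx], ad[idx], failed[idx] = 40, 2, "ab"
    ab = np.round(ad / dp, 4)
    calls = calls.assign(gq=np.round(gq, 2), dp=dp, ad_alt=ad, ab=ab,
                         zygosity="het")

    # ground-truth pass/fail at the reference discovery thresholds
    geno_pass = ((calls["gq"].to_numpy() >= _REF["gq"])
                 & (calls["ad_alt"].to_numpy() >= _REF["ad_alt"])
                 & (calls["dp"].to_numpy() >= _REF["dp"])
                 & (calls["ab"].to_numpy() >= _REF["ab"]))
    vq = variants.set_index("variant_id")
    site_q = vq.loc[calls["variant_id"], "site_quality"].to_numpy()
    scheme = vq.loc[calls["variant_id"], "quality_scheme"].to_numpy()
    cut = np.where(scheme == "vqslod", _REF["vqslod"], _REF["qual"])
    expected_pass = geno_pass & (site_q > cut)
    call_qc = pd.DataFrame({
        "sample_id": calls["sample_id"],
        "variant_id": calls["variant_id"],
        "failed_criterion": failed,
        "expected_pass": expected_pass,
    })

    dataset = validate_dataset(samples, variants, calls)
    truth = TruthTable(
        carriers=pd.DataFrame(
            truth_carriers, columns=["sample_id", "gene", "variant_id",
                                     "variant_class", "vest4", "planted"]),
        call_qc=call_qc,
        planted=pd.DataFrame(
            [{"gene": pg.gene,
              "case_carrier_rate": pg.case_carrier_rate,
              "control_carrier_rate": pg.control_carrier_rate,
              "lof_fraction": pg.lof_fraction}
             for pg in p.planted_genes],
            columns=["gene", "case_carrier_rate", "control_carrier_rate",
                     "lof_fraction"]),
    )
    return dataset, truth


def simulate_null_study(p: SimulationParams,
                        n_replicates: int) -> list[Dataset]:
    """Replicate datasets under the global null (no case enrichment)."""
    for pg in p.planted_genes:
        if pg.case_carrier_rate != pg.control_carrier_rate:
            raise ConfigError("null study requires equal case/control "
                              f"rates (gene {pg.gene})")
    out = []
    for i in range(n_replicates):
        d, _ = simulate_cohort(p.replace(seed=_spawn_seed(p.seed, i)))
        out.append(d)
    return out


@dataclass
class OperatingCharacteristics:
    type1: float
    power: float
    n_null_tests: int
    n_planted_tests: int
    results: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def estimate_operating_characteristics(
        p: SimulationParams, alpha: float, n_replicates: int,
        cfg: AnalysisConfig | None = None,
        tie_policy: str = "inclusive") -> OperatingCharacteristics:
    """Empirical type-I error and power of the full pipeline.

    Runs the variable-threshold scan plus rescanning permutation
    correction per gene per replicate; the rejection rate among unplanted
    genes estimates the type-I error and among planted genes the power, at
    the supplied ``alpha`` on the permutation-corrected p value.
    """
    if cfg is None:
        cfg = AnalysisConfig(n_permutations=1999, seed=p.seed)
    planted_names = {pg.gene for pg in p.planted_genes}
    rows = []
    for i in range(n_replicates):
        rep_seed = _spawn_seed(p.seed, i)
        d, _ = simulate_cohort(p.replace(seed=rep_seed))
        rep_cfg = cfg.replace(seed=rep_seed)
        for gene in p.gene_universe():
            p_perm = _burden.permutation_corrected_p(
                d, gene, rep_cfg, tie_policy=tie_policy,
                early_exit_r=max(200, int(5 * alpha * cfg.n_permutations)))
            rows.append({"replicate": i, "gene": gene,
                         "planted": gene in planted_names,
                         "p_permutation": p_perm,
                         "reject": p_perm < alpha})
    df = pd.DataFrame(rows)
    null = df[~df["planted"]]
    alt = df[df["planted"]]
    type1 = float(null["reject"].mean()) if len(null) else math.nan
    power = float(alt["reject"].mean()) if len(alt) else math.nan
    return OperatingCharacteristics(type1, power, len(null), len(alt), df)
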