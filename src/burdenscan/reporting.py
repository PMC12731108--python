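"""Diagnostic and result reporting: QQ data, lollipop data, run manifests.

Plots are emitted as plain data tables (TSV/JSON) rather than images, so
outputs are diffable and byte-reproducible; any plotting front end can
render them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort_io import AnalysisConfig, Dataset, GeneAnnotation
from .errors import ConfigError, ValidationError
from .qc import CalibrationReport

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class QQData:
    """Observed vs expected -log10 p with 95% pointwise bands.

    Arrays are ordered so expected values are non-decreasing (largest p
    first).  Bands come from Beta order-statistic quantiles: the k-th
    smallest of n uniform p values is Beta(k, n - k + 1) distributed.
    """
    ranks: np.ndarray
    expected_neglog10: np.ndarray
    observed_neglog10: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": self.ranks,
            "expected_neglog10": self.expected_neglog10,
            "observed_neglog10": self.observed_neglog10,
            "band_low": self.band_low,
            "band_high": self.band_high,
        })

    @property
    def fraction_in_band(self) -> float:
        inside = ((self.observed_neglog10 >= self.band_low)
                  & (self.observed_neglog10 <= self.band_high))
        return float(inside.mean())


def qq_data(pvalues) -> QQData:
    """Build QQ-plot data for a collection of p values in (0, 1]."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ConfigError("qq_data needs at least one p value")
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("p values must lie in (0, 1]")
    n = p.size
    order = np.sort(p)[::-1]                  # largest p first
    k = np.arange(n, 0, -1)                   # rank among ascending order
    expected = k / (n + 1.0)
    band_hi_p = stats.beta.ppf(0.975, k, n - k + 1)
    band_lo_p = stats.beta.ppf(0.025, k, n - k + 1)
    return QQData(
        ranks=k,
        expected_neglog10=-np.log10(expected),
        observed_neglog10=-np.log10(order),
        band_low=-np.log10(band_hi_p),
        band_high=-np.log10(band_lo_p),
    )


@dataclass
class LollipopData:
    """Variant counts along a protein with a domain track."""
    gene: str
    sites: pd.DataFrame        # protein_position, variant_class, cohort,
                               # count, domain
    domain_track: list[tuple[str, int, int]]

    def to_json(self) -> str:
        return json.dumps({
            "gene": self.gene,
            "sites": self.sites.to_dict(orient="records"),
            "domains": [{"name": n, "start": s, "end": e}
                        for n, s, e in self.domain_track],
        }, indent=2, sort_keys=True)


def _domain_for(position: int, ann: GeneAnnotation) -> str:
    for name, start, end in ann.domains:
        if start <= position <= end:
            return name
    return ""


def lollipop_data(gene: str, d: Dataset, ann: GeneAnnotation,
                  positions: dict[str, int]) -> LollipopData:
    """Aggregate per-site variant observation counts for a lollipop plot.

    ``positions`` maps variant_id to the 1-based protein position (protein
    coordinates are consumed as annotation, never computed from
    transcripts).  Counts are variant observations per (position, class,
    cohort); each site is labeled with the containing protein domain, if
    any.
    """
    v = d.variants[d.variants["gene"] == gene]
    missing = set(v["variant_id"]) - set(positions)
    if missing:
        raise ValidationError(
            f"{gene}: no protein position for variants {sorted(missing)[:5]}")
    cohort_of = d.samples.set_index("sample_id")["cohort"]
    obs = d.calls[d.calls["variant_id"].isin(set(v["variant_id"]))]
    obs = obs.drop_duplicates(["sample_id", "variant_id"])
    rows = []
    cls_of = v.set_index("variant_id")["variant_class"]
    for _, call in obs.iterrows():
        pos = int(positions[call["variant_id"]])
        if pos < 1:
            raise ValidationError(f"{gene}: protein position {pos} < 1")
        if ann.protein_length is not None and pos > ann.protein_length:
            raise ValidationError(
                f"{gene}: position {pos} exceeds protein length "
                f"{ann.protein_length}")
        rows.append({"protein_position": pos,
                     "variant_class": cls_of[call["variant_id"]],
                     "cohort": cohort_of[call["sample_id"]]})
    if rows:
        sites = (pd.DataFrame(rows)
                 .groupby(["protein_position", "variant_class", "cohort"])
                 .size().reset_index(name="count"))
    else:
        sites = pd.DataFrame(columns=["protein_position", "variant_class",
                                      "cohort", "count"])
    sites["domain"] = [_domain_for(p, ann)
                       for p in sites["protein_position"]]
    sites = sites.sort_values(
        ["protein_position", "variant_class", "cohort"]).reset_index(drop=True)
    return LollipopData(gene, sites, list(ann.domains))


RESULT_COLUMNS = [
    "gene", "variants_per_individual_cases",
    "variants_per_individual_controls", "relative_risk", "vest_threshold",
    "p_value", "most_significant_analysis", "analysis", "case_count",
    "control_count", "n_case", "n_control", "p_binomial", "p_permutation",
    "flag",
]


def results_frame(results) -> pd.DataFrame:
    """Burden results as a DataFrame in the standard column order."""
    df = pd.DataFrame([r.to_dict() for r in results])
    return df[RESULT_COLUMNS]


def write_report(results, calib: CalibrationReport | None,
                 thresholds: tuple[float, float],
                 out_dir: str | Path,
                 cfg: AnalysisConfig | None = None,
                 lollipops: list[LollipopData] | None = None) -> Path:
    """Write the consolidated run report; returns the output directory.

    Emits ``results.tsv`` (burden results, most-significant-analysis
    labels included), ``calibration.tsv``, ``qq_data.tsv`` (built from the
    per-analysis binomial p values), optional ``lollipop_<gene>.json``
    files, and ``manifest.yaml`` echoing the configuration, seed,
    significance thresholds, software version and row counts.  Re-running
    with identical inputs reproduces byte-identical files.
    """
    results = list(results)
    if not results:
        raise ConfigError("no results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    df = results_frame(results)
    df.to_csv(out_dir / "results.tsv", sep="\t", index=False,
              lineterminator="\n")

    if calib is not None:
        calib.to_frame().to_csv(out_dir / "calibration.tsv", sep="\t",
                                index=False, lineterminator="\n")

    qq = qq_data(df["p_binomial"].clip(lower=1e-300))
    qq.to_frame().to_csv(out_dir / "qq_data.tsv", sep="\t", index=False,
                         lineterminator="\n")

    for lp in lollipops or []:
        (out_dir / f"lollipop_{lp.gene}.json").write_text(lp.to_json())

    manifest = {
        "software": {"name": "burdenscan", "version": __version__},
        "seed": cfg.seed if cfg is not None else None,
        "config": ({k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in cfg.__dict__.items()}
                   if cfg is not None else None),
        "bonferroni_threshold": float(thresholds[0]),
        "borderline_threshold": float(thresholds[1]),
        "n_results": len(df),
        "n_genes": int(df["gene"].nunique()),
        "calibration_feasible": (bool(calib.feasible)
                                 if calib is not None else None),
    }
    (out_dir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True))
    log.info("report written to %s (%d results)", out_dir, len(df))
    return out_dir
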