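"""Shared fixtures: compact builders for small in-memory cohorts."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from burdenscan import validate_dataset

_CONSEQUENCE = {
    "lof": "stop_gained",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "inframe_indel": "inframe_insertion",
    "other": "intron_variant",
}


def build_dataset(n_case, n_control, observations, n_crc=None,
                  site_quality=10.0, quality_scheme="vqslod",
                  af=0.0, gq=60.0, dp=30, ad_alt=15, ab=0.5):
    """Assemble a validated Dataset from compact observation tuples.

    ``observations`` is an iterable of ``(sample_id, gene, variant_class,
    vest)`` with sample ids like ``case_00001`` / ``control_00001``; each
    tuple becomes one private variant carried by that sample.  ``n_crc``
    controls how many case samples get phenotype "crc" (default: all).
    """
    n_crc = n_case if n_crc is None else n_crc
    samples = pd.DataFrame({
        "sample_id": [f"case_{i:05d}" for i in range(1, n_case + 1)]
        + [f"control_{i:05d}" for i in range(1, n_control + 1)],
        "cohort": ["case"] * n_case + ["control"] * n_control,
        "phenotype": ["crc"] * n_crc + ["polyp"] * (n_case - n_crc)
        + ["control"] * n_control,
        "ancestry_label": "EUR",
        "kinship_cluster": "",
        "icd10_codes": "",
    })
    counter = itertools.count(1)
    v_rows, c_rows = [], []
    for sid, gene, cls, vest in observations:
        pos = next(counter)
        v_rows.append({
            "variant_id": f"chr1:{pos}:A:G", "gene": gene,
            "consequence": _CONSEQUENCE[cls], "vest4": vest,
            "af_gnomad": af, "af_ukbb": af, "site_quality": site_quality,
            "quality_scheme": quality_scheme})
        c_rows.append({"sample_id": sid, "variant_id": f"chr1:{pos}:A:G",
                       "gq": gq, "dp": dp, "ad_alt": ad_alt, "ab": ab,
                       "zygosity": "het"})
    cols_v = ["variant_id", "gene", "consequence", "vest4", "af_gnomad",
              "af_ukbb", "site_quality", "quality_scheme"]
    cols_c = ["sample_id", "variant_id", "gq", "dp", "ad_alt", "ab",
              "zygosity"]
    variants = pd.DataFrame(v_rows, columns=cols_v)
    calls = pd.DataFrame(c_rows, columns=cols_c)
    return validate_dataset(samples, variants, calls)


@pytest.fixture
def meikin_like():
    """Gene with 2 case missense (VEST 0.9, 0.11) + 2 case LoF carriers,
    no control carriers, in a 212-case / 31,699-control cohort with 174
    confirmed carcinomas."""
    obs = [("case_00001", "MEIKIN", "missense", 0.9),
           ("case_00002", "MEIKIN", "missense", 0.11),
           ("case_00003", "MEIKIN", "lof", None),
           ("case_00004", "MEIKIN", "lof", None)]
    return build_dataset(212, 31699, obs, n_crc=174)
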