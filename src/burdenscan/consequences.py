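"""Consequence-term to variant-class mapping.

The burden analysis distinguishes five variant classes:

``lof``
    predicted loss of function (stop gain, start/stop loss, frameshift,
    canonical splice disruption),
``missense``
    single amino-acid substitutions, scored for deleteriousness,
``synonymous`` and ``inframe_indel``
    functionally neutral classes used to calibrate cross-cohort QC,
``other``
    everything else (ignored by all tests).

The mapping lives in a shipped, user-editable YAML file
(``data/consequence_classes.yaml``); unknown terms map to ``other`` and are
logged once per term.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources

import yaml

VARIANT_CLASSES = ("lof", "missense", "synonymous", "inframe_indel", "other")

log = logging.getLogger(__name__)
_warned_terms: set[str] = set()


@lru_cache(maxsize=1)
def default_class_map() -> dict[str, str]:
    """Load the shipped consequence -> class mapping (term -> class)."""
    text = resources.files("burdenscan.data").joinpath(
        "consequence_classes.yaml").read_text()
    raw = yaml.safe_load(text)
    mapping: dict[str, str] = {}
    for cls, terms in raw.items():
        for term in terms:
            mapping[term] = cls
    return mapping


def classify_consequence(consequence: str,
                         class_map: dict[str, str] | None = None) -> str:
    """Map a transcript-consequence term to a variant class.

    Composite VEP terms joined with ``&`` are classified by their most
    severe member (lof > missense > inframe_indel > synonymous > other).
    Unknown terms return ``"other"`` and are logged once per term.
    """
    mapping = class_map if class_map is not None else default_class_map()
    terms = consequence.split("&") if "&" in consequence else [consequence]
    classes = []
    for term in terms:
        cls = mapping.get(term.strip())
        if cls is None:
            cls = "other"
            if term not in _warned_terms:
                _warned_terms.add(term)
                log.info("unmapped consequence term %r -> other", term)
        classes.append(cls)
    for cls in ("lof", "missense", "inframe_indel", "synonymous"):
        if cls in classes:
            return cls
    return "other"
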