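"""Published image counts of the public EBHI enteroscope-biopsy H&E dataset
(200x magnification subset) and the benign/malignant grouping rule.

The dataset itself (figshare DOI 10.6084/m9.figshare.16999363.v1) is never
required here; only its printed per-category counts are encoded so that the
binary-protocol arithmetic can be checked offline.
"""

from __future__ import annotations

from typing import Dict

EBHI_200X_COUNTS: Dict[str, int] = {
    "Normal": 61,
    "Polyp": 254,
    "Low-grade IN": 603,
    "High-grade IN": 130,
    "Adenocarcinoma": 790,
}

BINARY_GROUPS: Dict[str, str] = {
    "Normal": "benign",
    "Polyp": "benign",
    "Low-grade IN": "benign",
    "High-grade IN": "malignant",
    "Adenocarcinoma": "malignant",
}


def binary_counts(counts: Dict[str, int] | None = None) -> Dict[str, int]:
    """Apply the benign/malignant grouping and return per-super-class totals."""
    counts = EBHI_200X_COUNTS if counts is None else counts
    out = {"benign": 0, "malignant": 0}
    for category, n in counts.items():
        out[BINARY_GROUPS[category]] += n
    out["total"] = sum(counts.values())
    return out
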