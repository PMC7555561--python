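"""Built-in parameter tables and reference fixtures.

Two simulation designs with extensive within-item equality structure are
bundled: a dichotomous one (12 items, 4 latent classes) and a polytomous one
(12 four-category items, 4 classes).  Both specify parameters for six items
and duplicate them to items 7-12, and both carry class probabilities
(0.30, 0.20, 0.10, 0.40).  The first class has the lowest correct-response
probability on every item and the fourth the highest, so the generating
classes are partially ordered by proficiency.

Also bundled, as worked-example fixtures for the partial-order tooling: a
published five-class solution for the dichotomized SPM-LS data (the last 12
Raven's Standard Progressive Matrices items, N = 499) and the SPM-LS
distractor-frequency table used to recode polytomous responses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DICHOTOMOUS_CLASS_PROBS",
    "DICHOTOMOUS_ITEM_PROBS",
    "POLYTOMOUS_ITEM_TABLES",
    "SPM_LS_FIVE_CLASS_PROBS",
    "SPM_LS_FIVE_CLASS_WEIGHTS",
    "SPM_LS_ITEM_LABELS",
    "SPM_LS_DISTRACTOR_TABLE",
    "SPM_LS_OPTION_CODES",
    "synthetic_spm_ls_raw",
]

#: class membership probabilities shared by both simulation designs
DICHOTOMOUS_CLASS_PROBS = np.array([0.30, 0.20, 0.10, 0.40])
POLYTOMOUS_CLASS_PROBS = DICHOTOMOUS_CLASS_PROBS

#: correct-response probability per item type (items 1-6, duplicated to 7-12)
#: and class; dichotomous design
_DICHO_BASE = np.array(
    [
        [0.10, 0.82, 0.82, 0.82],
        [0.22, 0.88, 0.88, 0.88],
        [0.16, 0.79, 0.16, 0.79],
        [0.25, 0.85, 0.25, 0.85],
        [0.10, 0.10, 0.46, 0.91],
        [0.22, 0.22, 0.22, 0.79],
    ]
)
DICHOTOMOUS_ITEM_PROBS = np.vstack([_DICHO_BASE, _DICHO_BASE])

#: polytomous design: per item type a (K+1=4 categories) x (C=4 classes)
#: probability table; category 0 is the correct response
_POLY_BASE = [
    np.array(
        [
            [0.10, 0.82, 0.82, 0.82],
            [0.30, 0.06, 0.06, 0.06],
            [0.30, 0.06, 0.06, 0.06],
            [0.30, 0.06, 0.06, 0.06],
        ]
    ),
    np.array(
        [
            [0.22, 0.88, 0.88, 0.88],
            [0.26, 0.05, 0.04, 0.06],
            [0.26, 0.05, 0.04, 0.06],
            [0.26, 0.02, 0.04, 0.00],
        ]
    ),
    np.array(
        [
            [0.16, 0.79, 0.16, 0.79],
            [0.28, 0.11, 0.28, 0.11],
            [0.33, 0.05, 0.33, 0.05],
            [0.23, 0.05, 0.23, 0.05],
        ]
    ),
    np.array(
        [
            [0.25, 0.85, 0.25, 0.85],
            [0.35, 0.03, 0.35, 0.03],
            [0.20, 0.03, 0.20, 0.03],
            [0.20, 0.09, 0.20, 0.09],
        ]
    ),
    np.array(
        [
            [0.10, 0.10, 0.46, 0.91],
            [0.30, 0.30, 0.18, 0.03],
            [0.30, 0.30, 0.18, 0.03],
            [0.30, 0.30, 0.18, 0.03],
        ]
    ),
    np.array(
        [
            [0.22, 0.22, 0.22, 0.79],
            [0.24, 0.23, 0.22, 0.06],
            [0.20, 0.17, 0.12, 0.04],
            [0.34, 0.38, 0.44, 0.11],
        ]
    ),
]
POLYTOMOUS_ITEM_TABLES = _POLY_BASE + _POLY_BASE

SPM_LS_ITEM_LABELS = [f"SPM{i}" for i in range(1, 13)]

#: published five-class RLCA solution for the dichotomized SPM-LS data:
#: correct-response probabilities (12 items x 5 classes) ...
SPM_LS_FIVE_CLASS_PROBS = np.array(
    [
        [0.39, 0.39, 0.83, 0.83, 0.83],
        [0.57, 0.57, 0.99, 0.86, 0.99],
        [0.33, 0.00, 0.86, 0.96, 0.96],
        [0.05, 1.00, 0.91, 0.60, 1.00],
        [0.08, 1.00, 0.96, 0.77, 1.00],
        [0.07, 0.07, 0.85, 0.85, 0.97],
        [0.20, 0.83, 0.58, 0.83, 0.95],
        [0.06, 0.69, 0.36, 1.00, 0.90],
        [0.16, 0.34, 0.34, 1.00, 0.90],
        [0.00, 0.23, 0.23, 0.00, 0.79],
        [0.14, 0.00, 0.14, 0.00, 0.77],
        [0.11, 0.62, 0.11, 0.11, 0.62],
    ]
)
#: ... and the corresponding class probabilities
SPM_LS_FIVE_CLASS_WEIGHTS = np.array([0.12, 0.04, 0.40, 0.07, 0.37])

#: SPM-LS distractor analysis: per item, (percent frequency, original option
#: code) in recoded order — entry 0 is the correct option, entries 1.. the
#: distractors from most to least attractive.  Options never chosen are
#: absent; each item offers codes 1..8.
SPM_LS_OPTION_CODES = tuple(range(1, 9))


def synthetic_spm_ls_raw(n: int = 500):
    """Synthetic stand-in for the raw SPM-LS responses.

    The real dataset must be downloaded separately; this constructs, per
    item, a deterministic response column whose option frequencies match
    the published percentage table (counts rounded to 1/n resolution, the
    correct option absorbing the rounding remainder).  Marginal
    distributions are faithful; the person-level dependence structure is
    not, so this is only suitable for exercising recoding and frequency
    logic, not for refitting the published models.

    Returns ``(responses, key)``: an ``(n, 12)`` option-code matrix and
    the correct option per item.
    """
    responses = np.zeros((n, 12), dtype=np.int64)
    key = np.zeros(12, dtype=np.int64)
    for i, label in enumerate(SPM_LS_ITEM_LABELS):
        entries = SPM_LS_DISTRACTOR_TABLE[label]
        key[i] = entries[0][1]
        counts = [int(round(pct / 100.0 * n)) for pct, _ in entries]
        counts[0] += n - sum(counts)  # correct option absorbs rounding
        col = np.concatenate(
            [np.full(cnt, code, dtype=np.int64)
             for cnt, (_, code) in zip(counts, entries)]
        )
        # deterministic interleave so no row is all-correct or all-rare
        responses[:, i] = col[(np.arange(n) * 7919) % n]
    return responses, key
SPM_LS_DISTRACTOR_TABLE = {
    "SPM1": [(76.0, 7), (13.6, 3), (3.0, 1), (2.4, 4), (2.2, 6), (2.0, 2), (0.8, 5)],
    "SPM2": [(91.0, 6), (3.0, 3), (2.4, 4), (2.2, 1), (0.8, 5), (0.4, 7), (0.2, 2)],
    "SPM3": [(80.4, 8), (8.0, 2), (4.2, 6), (2.0, 4), (1.8, 3), (1.6, 5), (1.2, 7), (0.8, 1)],
    "SPM4": [(82.4, 2), (5.6, 3), (3.2, 5), (2.6, 1), (2.2, 8), (1.8, 6), (1.2, 7), (1.0, 4)],
    "SPM5": [(85.6, 1), (3.8, 2), (3.0, 3), (2.6, 7), (1.8, 6), (1.6, 5), (1.0, 4), (0.6, 8)],
    "SPM6": [(76.4, 5), (7.0, 4), (5.2, 6), (3.0, 3), (2.8, 7), (2.6, 8), (2.0, 2), (1.0, 1)],
    "SPM7": [(70.1, 1), (6.6, 4), (5.8, 5), (5.4, 3), (4.4, 8), (3.4, 6), (2.4, 7), (1.8, 2)],
    "SPM8": [(58.1, 6), (7.6, 1), (7.0, 3), (6.6, 8), (6.4, 2), (6.2, 5), (5.8, 7), (2.2, 4)],
    "SPM9": [(57.3, 3), (12.0, 5), (9.0, 1), (7.2, 4), (6.6, 8), (4.0, 7), (3.0, 2), (0.8, 6)],
    "SPM10": [(39.5, 2), (17.2, 6), (11.2, 7), (8.0, 3), (7.8, 8), (7.4, 5), (6.0, 4), (2.8, 1)],
    "SPM11": [(35.7, 4), (14.0, 1), (13.8, 7), (9.8, 5), (9.4, 6), (8.0, 3), (6.6, 2), (2.6, 8)],
    "SPM12": [(32.5, 5), (15.4, 2), (14.2, 3), (10.4, 1), (8.2, 4), (8.2, 7), (7.4, 6), (3.6, 8)],
}
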