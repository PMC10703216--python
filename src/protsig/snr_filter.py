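"""Signal-to-noise-ratio ranking of proteins between two classes.

For each protein the score is SNR = (mu1 - mu2) / (sigma1 + sigma2), the
Golub-style two-group separation statistic: class means divided by the sum
of class standard deviations (sample, n-1 convention).  Selection keeps
proteins whose |SNR| strictly exceeds a threshold (0.4 in the reference
workflow), ordered by decreasing magnitude.  SNR is a ranking filter, not a
hypothesis test; no multiplicity correction applies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_preprocess import InputError, ProteinMatrix

__all__ = ["compute_snr", "snr_select"]


def compute_snr(pm: ProteinMatrix) -> pd.DataFrame:
    """Score every protein by its two-class signal-to-noise ratio.

    Returns a DataFrame indexed by protein with columns ``mu1``, ``mu2``,
    ``sigma1``, ``sigma2``, ``snr``; class 1 is the first declared class
    label of ``pm``.  A protein constant in both classes has an undefined
    ratio, reported as NaN.  Missing entries must have been imputed.

    Raises
    ------
    InputError
        If either class has fewer than two samples.
    """
    if pm.classes is not None:
        c1, c2 = pm.classes
    else:
        labels = sorted(pm.class_labels.unique())
        if len(labels) != 2:
            raise InputError(f"expected exactly 2 class labels, got {labels}")
        c1, c2 = labels
    g1 = pm.values.loc[pm.class_labels == c1]
    g2 = pm.values.loc[pm.class_labels == c2]
    for name, g in ((c1, g1), (c2, g2)):
        if len(g) < 2:
            raise InputError(f"class {name!r} has {len(g)} samples; need >= 2")
    mu1, mu2 = g1.mean(axis=0), g2.mean(axis=0)
    s1, s2 = g1.std(axis=0, ddof=1), g2.std(axis=0, ddof=1)
    denom = s1 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = (mu1 - mu2) / denom
    snr[denom == 0] = np.nan
    return pd.DataFrame(
        {"mu1": mu1, "mu2": mu2, "sigma1": s1, "sigma2": s2, "snr": snr}
    ).rename_axis("protein_id")


def snr_select(
    scores: pd.DataFrame, threshold: float = 0.4, use_abs: bool = True
) -> list[str]:
    """Proteins whose SNR strictly exceeds ``threshold``, strongest first.

    With ``use_abs`` (default) the magnitude |SNR| is compared, so proteins
    elevated in either class qualify; otherwise only the signed score is
    compared.  Undefined (NaN) scores are never retained.
    """
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    snr = scores["snr"]
    crit = snr.abs() if use_abs else snr
    keep = scores.index[(crit > threshold) & snr.notna()]
    order = snr.loc[keep].abs().sort_values(ascending=False, kind="mergesort")
    return list(order.index)
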