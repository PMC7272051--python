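"""Rigid-body superposition helpers."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``reference``.

    The optimal rotation/translation is fitted on ``indices`` (all atoms by
    default), optionally weighted (e.g. by mass), and applied to every atom.
    Returns the transformed copy of ``mobile``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if indices is None else np.asarray(indices)
    w = np.ones(len(sel)) if weights is None else np.asarray(weights, dtype=float)
    mob_sel = mobile[sel]
    ref_sel = reference[sel]
    mob_center = np.average(mob_sel, axis=0, weights=w)
    ref_center = np.average(ref_sel, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(ref_sel - ref_center, mob_sel - mob_center, weights=w)
    return rot.apply(mobile - mob_center) + ref_center
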