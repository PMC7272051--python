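"""Dynamic cross-correlation and group flexibility profiles.

The DCCM entry for a Cα pair is the normalized covariance of their
displacement vectors about the ensemble mean,

    C(i,j) = <Δr_i · Δr_j> / (<Δr_i²>^½ <Δr_j²>^½),

evaluated over the concatenated frames of every trajectory in a motion
group (one map per motion class).  Fully in-phase pairs score +1,
anti-phase pairs −1.

Group flexibility is the per-atom root-mean-square displacement from the
initial structure, averaged over the three Cartesian degrees of freedom of
the atom, the frames of each mode, and the modes of the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import superpose
from .nma import ModeTrajectory
from .structures import CalphaSelection, ResidueKey

__all__ = [
    "ModeGroup",
    "CrossCorrelationMatrix",
    "FlexibilityProfile",
    "compute_dccm",
    "compute_group_rmsf",
    "coupling_class",
]

# reporting bins for |C|: below 0.5 weak, 0.5-0.7 moderate, >= 0.7 strong
MODERATE_COUPLING = 0.5
STRONG_COUPLING = 0.7


class CorrelationError(ValueError):
    pass


@dataclass
class ModeGroup:
    """A set of same-system mode trajectories treated as one motion class."""

    group_id: str
    trajectories: list[ModeTrajectory]
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise CorrelationError(f"mode group {self.group_id!r} is empty")
        ref = self.trajectories[0].reference
        for trj in self.trajectories:
            if trj.reference.n_atoms != ref.n_atoms or not np.allclose(
                trj.reference.coord, ref.coord
            ):
                raise CorrelationError(
                    f"mode group {self.group_id!r}: trajectories do not share "
                    "a reference structure"
                )

    @property
    def n_modes(self) -> int:
        return len(self.trajectories)

    @property
    def mode_labels(self) -> list[int]:
        return [t.mode_label for t in self.trajectories]


@dataclass
class CrossCorrelationMatrix:
    matrix: np.ndarray  # (n, n); NaN rows for zero-fluctuation atoms
    residue_keys: list[ResidueKey]
    n_frames: int
    source_modes: list[int]
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = np.zeros(len(self.residue_keys), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        labels = [str(k) for k in self.residue_keys]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), float_format="%.10g")

    def to_heatmap(self, path: str | Path, title: str = "") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.matrix, vmin=-1, vmax=1, cmap="RdBu_r", origin="lower")
        fig.colorbar(im, ax=ax, label="C(i,j)")
        ax.set_xlabel("residue index")
        ax.set_ylabel("residue index")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)


@dataclass
class FlexibilityProfile:
    rmsf: np.ndarray  # per Cα, Å
    residue_keys: list[ResidueKey]
    group_id: str
    n_modes: int

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("residue\trmsf_A\n")
            for key, value in zip(self.residue_keys, self.rmsf):
                fh.write(f"{key}\t{value:.6f}\n")


def coupling_class(c: float) -> str:
    """Reporting bin for a correlation magnitude: weak / moderate / strong."""
    a = abs(c)
    if a >= STRONG_COUPLING:
        return "strong"
    if a >= MODERATE_COUPLING:
        return "moderate"
    return "weak"


def _gather_frames(
    group: ModeGroup,
    selection: CalphaSelection,
    fit: bool,
) -> np.ndarray:
    """Stack selected-atom coordinates of every frame, optionally
    superposing each full frame onto the reference on the selection."""
    indices = np.asarray(selection.indices)
    ref = group.trajectories[0].reference.coord
    stacks = []
    for trj in group.trajectories:
        for f in range(trj.n_frames):
            frame = trj.frames[f]
            if fit:
                frame = superpose(frame, ref, indices=indices)
            stacks.append(frame[indices])
    return np.asarray(stacks)


def compute_dccm(
    group: ModeGroup,
    selection: CalphaSelection,
    fit: bool = True,
) -> CrossCorrelationMatrix:
    """Cross-correlation map over the concatenated frames of a motion group.

    Frames are least-squares superposed onto the reference on the selection
    first (a no-op for unrelaxed trajectories, a safeguard for relaxed
    ones); displacements are taken about the ensemble mean position.
    Atoms with zero fluctuation get NaN rows and are flagged in
    ``undefined`` instead of being silently zeroed.
    """
    coords = _gather_frames(group, selection, fit)
    n_frames = len(coords)
    if n_frames < 2:
        raise CorrelationError("need at least two frames for a correlation matrix")
    delta = coords - coords.mean(axis=0)
    covariance = np.einsum("fid,fjd->ij", delta, delta) / n_frames
    variance = np.diag(covariance).copy()
    undefined = variance <= 1e-30
    scale = np.sqrt(np.where(undefined, 1.0, variance))
    matrix = covariance / scale[:, None] / scale[None, :]
    matrix = np.clip(matrix, -1.0, 1.0)
    matrix[undefined, :] = np.nan
    matrix[:, undefined] = np.nan
    idx = np.where(~undefined)[0]
    matrix[idx, idx] = 1.0
    return CrossCorrelationMatrix(
        matrix=matrix,
        residue_keys=list(selection.residue_keys),
        n_frames=n_frames,
        source_modes=group.mode_labels,
        undefined=undefined,
    )


def compute_group_rmsf(
    group: ModeGroup,
    selection: CalphaSelection,
    fit: bool = True,
) -> FlexibilityProfile:
    """Per-Cα flexibility of a motion group.

    For each mode, the squared deviation of each selected atom from the
    initial structure is averaged over the mode's frames and the atom's
    three degrees of freedom; the profile is the square root of the average
    over the group's modes.  Duplicating a member leaves the profile
    unchanged.
    """
    indices = np.asarray(selection.indices)
    ref = group.trajectories[0].reference.coord
    ref_sel = ref[indices]
    msd_per_mode = []
    for trj in group.trajectories:
        frames = trj.frames
        if fit:
            frames = np.array([superpose(f, ref, indices=indices) for f in frames])
        deltas = frames[:, indices, :] - ref_sel  # (F, n, 3)
        msd = np.mean(np.sum(deltas**2, axis=2) / 3.0, axis=0)  # (n,)
        msd_per_mode.append(msd)
    profile = np.sqrt(np.mean(msd_per_mode, axis=0))
    return FlexibilityProfile(
        rmsf=profile,
        residue_keys=list(selection.residue_keys),
        group_id=group.group_id,
        n_modes=group.n_modes,
    )
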