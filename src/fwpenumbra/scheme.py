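"""Single-shell diffusion acquisition schemes and FSL bval/bvec I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

B0_THRESHOLD = 50.0  # s/mm^2 below which a volume counts as b=0


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values (s/mm^2) and unit gradient directions for one shell.

    Invariants: all non-zero b-values equal (single shell); gradients
    for b>0 are unit vectors; at least six unique directions.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs length mismatch")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        dw = bvals > B0_THRESHOLD
        if dw.any():
            shell = bvals[dw]
            if not np.allclose(shell, shell[0], rtol=1e-3):
                raise ValueError("multiple non-zero shells; single-shell scheme required")
            norms = np.linalg.norm(bvecs[dw], axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("diffusion gradients must be unit vectors")
            uniq = np.unique(np.round(bvecs[dw], 6), axis=0)
            if uniq.shape[0] < 6:
                raise ValueError("need at least six unique gradient directions")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def shell_bvalue(self) -> float:
        return float(self.bvals[self.dwi_mask][0])

    def __len__(self) -> int:
        return self.bvals.shape[0]

    # ---- FSL dialect text I/O (3 rows x N columns for bvec) ----
    def to_files(self, bval_path, bvec_path) -> None:
        Path(bval_path).write_text(" ".join(f"{b:g}" for b in self.bvals) + "\n")
        rows = [" ".join(f"{v:.6f}" for v in self.bvecs[:, ax]) for ax in range(3)]
        Path(bvec_path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_files(cls, bval_path, bvec_path) -> "AcquisitionScheme":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)


# 12 unit directions from antipodally-symmetric electrostatic repulsion
# (minimum pairwise separation ~38.9 deg); no two are collinear, so all
# twelve measurements are distinct.
_DIRECTIONS_12 = np.array([
    (+0.002707, +0.018085, +0.999833),
    (+0.654980, +0.086966, +0.750625),
    (-0.016951, -0.643035, +0.765649),
    (-0.723475, +0.669397, +0.168795),
    (+0.110797, -0.993725, +0.015334),
    (+0.162801, +0.755273, +0.634869),
    (+0.760838, +0.587178, +0.276313),
    (-0.516284, -0.800317, +0.304868),
    (-0.478921, +0.456258, +0.749976),
    (-0.725997, -0.210338, +0.654742),
    (-0.999594, +0.028114, +0.004539),
    (+0.635322, -0.574155, +0.516441),
])


def default_scheme(n_b0: int = 4, bvalue: float = 1000.0) -> AcquisitionScheme:
    """12-direction b=1000 s/mm^2 shell plus four b=0 volumes."""
    v = _DIRECTIONS_12.copy()
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(v), bvalue)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), v])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)
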