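"""Core in-memory container binding a 4D signal array to a gradient scheme."""

from __future__ import annotations

import dataclasses

import numpy as np

from .sampling import GradientScheme

__all__ = ["DWIVolume"]


@dataclasses.dataclass
class DWIVolume:
    """A 4D diffusion-weighted volume bound to a :class:`GradientScheme`.

    The fourth axis holds ``scheme.n_b0`` unweighted volumes first,
    followed by the ``scheme.n`` diffusion-weighted volumes in the
    scheme's storage order.
    """

    data: np.ndarray  # (X, Y, Z, n_b0 + N)
    scheme: GradientScheme
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, volume)")
        expected = self.scheme.n_b0 + self.scheme.n
        if self.data.shape[3] != expected:
            raise ValueError(
                f"4th dimension is {self.data.shape[3]} but scheme expects "
                f"{self.scheme.n_b0} b0 + {self.scheme.n} weighted volumes")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def b0(self) -> np.ndarray:
        """The unweighted volumes, shape (X, Y, Z, n_b0)."""
        return self.data[..., : self.scheme.n_b0]

    @property
    def weighted(self) -> np.ndarray:
        """The diffusion-weighted volumes, shape (X, Y, Z, N)."""
        return self.data[..., self.scheme.n_b0:]

    def copy(self) -> "DWIVolume":
        return DWIVolume(data=self.data.copy(), scheme=self.scheme,
                         affine=self.affine.copy())
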