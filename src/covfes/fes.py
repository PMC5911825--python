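"""Free-energy surfaces on regular 1D/2D grids.

A surface stores free energies A (kcal/mol) at bin centers, a boolean mask
marking empty (undefined) bins, and the temperature at which A was derived.
Unmasked values are referenced so that the global minimum is zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE

__all__ = ["FreeEnergySurface"]


@dataclass
class FreeEnergySurface:
    """Binned free-energy surface A(ξ) or A(ξx, ξy).

    Parameters
    ----------
    centers
        Tuple of per-axis bin-center arrays (one array for 1D, two for 2D).
    values
        Free energies, shape ``(nx,)`` or ``(nx, ny)``, kcal/mol. Entries at
        masked bins are ignored.
    mask
        Boolean array, same shape as ``values``; True marks an empty bin.
    temperature
        Temperature (K) used in the Boltzmann relation that produced A.
    """

    centers: tuple[np.ndarray, ...]
    values: np.ndarray
    mask: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = tuple(np.asarray(c, dtype=float) for c in self.centers)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = tuple(len(c) for c in self.centers)
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(
                f"shape mismatch: centers imply {expected}, "
                f"values {self.values.shape}, mask {self.mask.shape}"
            )
        if self.mask.all():
            raise ValueError("surface has no unmasked bins")

    @property
    def ndim(self) -> int:
        return len(self.centers)

    def min_referenced(self) -> "FreeEnergySurface":
        """Return a copy with the unmasked minimum shifted to zero."""
        shifted = self.values - self.values[~self.mask].min()
        return FreeEnergySurface(
            self.centers, shifted, self.mask.copy(), self.temperature, dict(self.meta)
        )

    def min_cell(self) -> tuple[int, ...]:
        """Index of the unmasked global-minimum bin."""
        vals = np.where(self.mask, np.inf, self.values)
        return tuple(int(i) for i in np.unravel_index(np.argmin(vals), vals.shape))

    def to_tsv(self) -> str:
        """Serialize as tab-separated ``center_x [center_y] A mask`` rows."""
        buf = io.StringIO()
        buf.write(f"# temperature_K\t{self.temperature}\n")
        if self.ndim == 1:
            buf.write("# columns\tcenter_x\tA\tmask\n")
            for i, cx in enumerate(self.centers[0]):
                buf.write(f"{cx:.10g}\t{self.values[i]:.10g}\t{int(self.mask[i])}\n")
        else:
            buf.write("# columns\tcenter_x\tcenter_y\tA\tmask\n")
            for i, cx in enumerate(self.centers[0]):
                for j, cy in enumerate(self.centers[1]):
                    buf.write(
                        f"{cx:.10g}\t{cy:.10g}\t{self.values[i, j]:.10g}"
                        f"\t{int(self.mask[i, j])}\n"
                    )
        return buf.getvalue()

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, text_or_path) -> "FreeEnergySurface":
        """Parse a surface previously produced by :meth:`to_tsv`."""
        if isinstance(text_or_path, str) and "\n" in text_or_path:
            text = text_or_path
        else:
            with open(text_or_path) as fh:
                text = fh.read()
        temperature = DEFAULT_TEMPERATURE
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "temperature_K":
                    temperature = float(parts[1])
                continue
            rows.append([float(tok) for tok in line.split()])
        if not rows:
            raise ValueError("empty FES table")
        ncol = len(rows[0])
        arr = np.asarray(rows, dtype=float)
        if ncol == 3:  # 1D
            cx = np.unique(arr[:, 0])
            values = np.full(len(cx), np.nan)
            mask = np.ones(len(cx), dtype=bool)
            idx = np.searchsorted(cx, arr[:, 0])
            values[idx] = arr[:, 1]
            mask[idx] = arr[:, 2].astype(bool)
            return cls((cx,), values, mask, temperature)
        cx = np.unique(arr[:, 0])
        cy = np.unique(arr[:, 1])
        values = np.full((len(cx), len(cy)), np.nan)
        mask = np.ones((len(cx), len(cy)), dtype=bool)
        ix = np.searchsorted(cx, arr[:, 0])
        iy = np.searchsorted(cy, arr[:, 1])
        values[ix, iy] = arr[:, 2]
        mask[ix, iy] = arr[:, 3].astype(bool)
        return cls((cx, cy), values, mask, temperature)
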