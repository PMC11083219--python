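"""Binned energy spectra -- the common currency between source, focal plane
and detector outputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpectrumHistogram:
    """Weighted counts versus energy on a fixed bin grid (keV)."""

    bin_edges: np.ndarray
    counts: np.ndarray = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.counts is None:
            self.counts = np.zeros(len(self.bin_edges) - 1)
        else:
            self.counts = np.asarray(self.counts, dtype=float)
            if len(self.counts) != len(self.bin_edges) - 1:
                raise ValueError("counts length must be n_edges - 1")

    @classmethod
    def regular(cls, e_min: float, e_max: float, bin_width: float) -> "SpectrumHistogram":
        n = int(round((e_max - e_min) / bin_width))
        return cls(np.linspace(e_min, e_max, n + 1))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def fill(self, energies, weights=None) -> None:
        h, _ = np.histogram(energies, bins=self.bin_edges, weights=weights)
        self.counts += h

    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> "SpectrumHistogram":
        tot = self.counts.sum()
        return SpectrumHistogram(self.bin_edges, self.counts / tot if tot else self.counts)

    def peak_energy(self) -> float:
        """Center of the maximum bin."""
        return float(self.centers[int(np.argmax(self.counts))])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw energies from the histogram (uniform within each bin)."""
        p = self.counts / self.counts.sum()
        idx = rng.choice(len(p), size=n, p=p)
        lo = self.bin_edges[idx]
        return lo + rng.random(n) * self.widths[idx]

    def to_csv(self, path, header: str = "energy_kev,counts") -> None:
        arr = np.column_stack([self.centers, self.counts])
        np.savetxt(path, arr, delimiter=",", header=header, comments="# ")

    def copy(self) -> "SpectrumHistogram":
        return SpectrumHistogram(self.bin_edges.copy(), self.counts.copy())
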