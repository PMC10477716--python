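"""Excitation-emission matrix (EEM) handling.

An EEM records fluorescence intensity over a grid of excitation (ex) and
emission (em) wavelengths. This module holds the shared container
(:class:`EEMCube`), Raman-area normalization and blank subtraction
(:func:`correct_eems`), and the scalar indices BIX, HIX and FI computed
from corrected spectra (:func:`compute_indices`).

Conventions
-----------
* Instrument lattice: ex 200-450 nm in 5 nm steps (51 points), em 250-600 nm
  in 1 nm steps (351 points).
* Missing cells (excised scatter) are stored as NaN and only appear in
  corrected cubes.
* Intensities of corrected cubes are in Raman units (normalized by the
  Raman peak area of the blank at ex = 350 nm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Default instrument wavelength lattices (nm).
EX_GRID = np.arange(200.0, 450.0 + 1e-9, 5.0)
EM_GRID = np.arange(250.0, 600.0 + 1e-9, 1.0)

#: Raman integration window (em, nm) at ex = 350 nm. The excitation wavelength
#: is fixed by the correction procedure; the emission window is the common
#: water-Raman band convention and is configurable.
RAMAN_EX = 350.0
RAMAN_EM_WINDOW = (371.0, 428.0)


@dataclass
class EEMCube:
    """A set of EEMs on a shared wavelength lattice.

    Parameters
    ----------
    sample_ids : list of str
    ex_grid, em_grid : ascending wavelength grids (nm)
    intensities : array, shape (n_samples, n_em, n_ex)
        Fluorescence intensities; NaN marks missing (excised) cells.
    corrected : bool
        True once Raman-normalized, blank-subtracted and scatter-excised.
    provenance : dict
        Correction metadata (blank id, Raman area, excised/clipped counts).
    """

    sample_ids: list[str]
    ex_grid: np.ndarray
    em_grid: np.ndarray
    intensities: np.ndarray
    corrected: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ex_grid = np.asarray(self.ex_grid, dtype=float)
        self.em_grid = np.asarray(self.em_grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.ex_grid) <= 0):
            raise ValueError("ex_grid must be strictly increasing")
        if np.any(np.diff(self.em_grid) <= 0):
            raise ValueError("em_grid must be strictly increasing")
        expect = (len(self.sample_ids), len(self.em_grid), len(self.ex_grid))
        if self.intensities.shape != expect:
            raise ValueError(
                f"intensities shape {self.intensities.shape} != (samples, em, ex) {expect}"
            )
        if not self.corrected and np.isnan(self.intensities).any():
            raise ValueError("missing cells are only allowed in corrected cubes")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample(self, sample_id: str) -> np.ndarray:
        """Return one sample's em x ex intensity grid."""
        return self.intensities[self.sample_ids.index(sample_id)]

    # ------------------------------------------------------------------ I/O
    def to_dir(self, out_dir: str | Path) -> None:
        """Write one CSV per sample (first column em nm, header row ex nm)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(self.sample_ids):
            df = pd.DataFrame(
                self.intensities[i], index=self.em_grid, columns=self.ex_grid
            )
            df.index.name = "em_nm"
            df.to_csv(out_dir / f"{sid}.csv")
        meta = {
            "sample_ids": self.sample_ids,
            "corrected": self.corrected,
            "provenance": self.provenance,
        }
        (out_dir / "cube.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "EEMCube":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "cube.json").read_text())
        mats, ex_grid, em_grid = [], None, None
        for sid in meta["sample_ids"]:
            df = pd.read_csv(in_dir / f"{sid}.csv", index_col=0)
            ex_grid = df.columns.astype(float).to_numpy()
            em_grid = df.index.to_numpy(dtype=float)
            mats.append(df.to_numpy(dtype=float))
        return cls(
            sample_ids=list(meta["sample_ids"]),
            ex_grid=ex_grid,
            em_grid=em_grid,
            intensities=np.stack(mats),
            corrected=meta["corrected"],
            provenance=meta.get("provenance", {}),
        )


def _check_same_grids(a: EEMCube, b: EEMCube) -> None:
    if not np.array_equal(a.ex_grid, b.ex_grid):
        raise ValueError("excitation grids differ between sample cube and blank")
    if not np.array_equal(a.em_grid, b.em_grid):
        raise ValueError("emission grids differ between sample cube and blank")


def raman_area(
    blank: EEMCube,
    ex: float = RAMAN_EX,
    em_window: tuple[float, float] = RAMAN_EM_WINDOW,
) -> float:
    """Raman peak area of a blank EEM at the given excitation wavelength.

    Trapezoidal integral of the blank's emission scan at ``ex`` over
    ``em_window``. The result defines the Raman-unit basis used to normalize
    sample EEMs.
    """
    if blank.n_samples != 1:
        raise ValueError("raman_area expects a single-sample blank cube")
    cols = np.nonzero(np.isclose(blank.ex_grid, ex))[0]
    if cols.size == 0:
        raise ValueError(f"blank has no ex={ex} nm column")
    lo, hi = em_window
    sel = (blank.em_grid >= lo) & (blank.em_grid <= hi)
    y = blank.intensities[0, sel, cols[0]]
    x = blank.em_grid[sel]
    if np.isnan(y).all():
        raise ValueError(
            f"non-positive Raman area: all-missing window for blank {blank.sample_ids[0]}"
        )
    area = float(np.trapezoid(np.nan_to_num(y), x))
    if not np.isfinite(area) or area <= 0:
        raise ValueError(
            f"non-positive Raman area ({area}) for blank {blank.sample_ids[0]}"
        )
    return area


def correct_eems(
    samples: EEMCube,
    blank: EEMCube,
    scatter_bandwidth: float = 10.0,
    raman_ex: float = RAMAN_EX,
    raman_em_window: tuple[float, float] = RAMAN_EM_WINDOW,
) -> EEMCube:
    """Raman-normalize, blank-subtract and scatter-excise sample EEMs.

    Steps, in order:

    1. divide samples and blank by the blank's Raman peak area at
       ``raman_ex`` (so corrected intensities are in Raman units);
    2. subtract the normalized blank from each normalized sample;
    3. excise residual first- and second-order Rayleigh bands
       (|em - ex| <= bw and |em - 2 ex| <= bw) to missing (NaN) — excised
       cells are down-weighted downstream, never interpolated;
    4. clip remaining negative cells to 0, counting them.

    Raises on grid mismatch or if either cube is already corrected.
    """
    if samples.corrected:
        raise ValueError("cube is already corrected (correction is not idempotent)")
    if blank.corrected:
        raise ValueError("blank must be an uncorrected raw EEM")
    _check_same_grids(samples, blank)
    area = raman_area(blank, ex=raman_ex, em_window=raman_em_window)

    norm = samples.intensities / area
    blank_norm = blank.intensities[0] / area
    sub = norm - blank_norm[None, :, :]

    em = samples.em_grid[:, None]
    ex = samples.ex_grid[None, :]
    scatter = (np.abs(em - ex) <= scatter_bandwidth) | (
        np.abs(em - 2.0 * ex) <= scatter_bandwidth
    )
    n_excised = int(scatter.sum()) * samples.n_samples
    sub[:, scatter] = np.nan

    neg = sub < 0
    n_clipped = int(np.nansum(neg))
    sub[neg] = 0.0

    return EEMCube(
        sample_ids=list(samples.sample_ids),
        ex_grid=samples.ex_grid.copy(),
        em_grid=samples.em_grid.copy(),
        intensities=sub,
        corrected=True,
        provenance={
            "blank_id": blank.sample_ids[0],
            "raman_area": area,
            "excised_cells": n_excised,
            "clipped_cells": n_clipped,
            "scatter_bandwidth_nm": scatter_bandwidth,
        },
    )


def _ex_column(cube: EEMCube, ex: float) -> np.ndarray:
    """Emission scan at excitation ``ex`` for all samples.

    Wavelengths off the 5-nm lattice (e.g. ex = 254) are obtained by linear
    interpolation between the bracketing columns.
    """
    grid = cube.ex_grid
    if ex < grid[0] or ex > grid[-1]:
        raise ValueError(f"ex={ex} nm outside grid range")
    j = int(np.searchsorted(grid, ex))
    if np.isclose(grid[min(j, len(grid) - 1)], ex):
        return cube.intensities[:, :, min(j, len(grid) - 1)]
    lo, hi = j - 1, j
    w = (ex - grid[lo]) / (grid[hi] - grid[lo])
    return (1 - w) * cube.intensities[:, :, lo] + w * cube.intensities[:, :, hi]


def _em_value(scan: np.ndarray, em_grid: np.ndarray, em: float) -> np.ndarray:
    idx = np.nonzero(np.isclose(em_grid, em))[0]
    if idx.size == 0:
        raise ValueError(f"em={em} nm not on grid")
    return scan[:, idx[0]]


def _band_sum(scan: np.ndarray, em_grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    sel = (em_grid >= lo) & (em_grid <= hi)
    return np.nansum(scan[:, sel], axis=1)


def compute_indices(cube: EEMCube, bix_autochthonous_threshold: float = 0.8) -> pd.DataFrame:
    """Per-sample fluorescence indices from a corrected EEM cube.

    BIX  = F(em 380) / F(em 430) at ex 310 — proportion of recently produced,
    microbially derived (autochthonous) organic matter; values above 0.8
    indicate autochthonous origin.

    HIX  = sum F(em 435-480) / (sum F(em 300-345) + sum F(em 435-480)) at
    ex 254 (interpolated between the 250 and 255 nm columns) — degree of
    humification, in [0, 1] by construction.

    FI   = F(em 450) / F(em 500) at ex 370 (McKnight-style fluorescence
    index distinguishing microbial from terrestrial precursor material).

    Zero denominators yield NaN with a warning rather than an exception.
    """
    if not cube.corrected:
        raise ValueError("indices are defined on corrected cubes only")
    em = cube.em_grid

    scan310 = _ex_column(cube, 310.0)
    bix_num = _em_value(scan310, em, 380.0)
    bix_den = _em_value(scan310, em, 430.0)

    scan254 = _ex_column(cube, 254.0)
    hix_high = _band_sum(scan254, em, 435.0, 480.0)
    hix_low = _band_sum(scan254, em, 300.0, 345.0)
    hix_den = hix_high + hix_low

    scan370 = _ex_column(cube, 370.0)
    fi_num = _em_value(scan370, em, 450.0)
    fi_den = _em_value(scan370, em, 500.0)

    def _ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
        out = np.full(len(num), np.nan)
        ok = np.isfinite(den) & (den > 0) & np.isfinite(num)
        out[ok] = num[ok] / den[ok]
        if (~ok).any():
            warnings.warn(
                f"{name}: zero or missing denominator for "
                f"{int((~ok).sum())} sample(s); reported as missing",
                stacklevel=3,
            )
        return out

    bix = _ratio(bix_num, bix_den, "BIX")
    hix = _ratio(hix_high, hix_den, "HIX")
    fi = _ratio(fi_num, fi_den, "FI")

    df = pd.DataFrame(
        {"BIX": bix, "HIX": hix, "FI": fi}, index=pd.Index(cube.sample_ids, name="sample")
    )
    origin = np.where(df["BIX"] > bix_autochthonous_threshold, "autochthonous", "allochthonous")
    df["origin"] = np.where(np.isfinite(df["BIX"]), origin, "unknown")
    return df
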