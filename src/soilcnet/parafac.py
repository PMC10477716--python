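"""Non-negative PARAFAC decomposition of corrected EEM cubes.

PARAFAC models a sample x emission x excitation fluorescence cube as a sum
of R trilinear components,

    X[i, j, k] = sum_r score[i, r] * em_load[j, r] * ex_load[k, r] + E,

with all factors non-negative. Fitting is alternating least squares with an
exact non-negative solve per mode; cells excised as scatter (NaN) are
excluded from the loss by EM-style imputation (each sweep imputes them with
the current model, which keeps the observed-cell loss monotonically
non-increasing). Validation follows the split-half scheme: models fitted on
random half-samples must agree with Tucker congruence > 0.95 on both the
excitation and emission loadings of every matched component pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

from .eem import EEMCube


@dataclass
class PARAFACModel:
    """Fitted trilinear model: unit-norm loadings, magnitude in the scores."""

    n_components: int
    ex_grid: np.ndarray
    em_grid: np.ndarray
    ex_loadings: np.ndarray  # (n_ex, R), unit-norm columns
    em_loadings: np.ndarray  # (n_em, R), unit-norm columns
    scores: np.ndarray  # (n_samples, R), non-negative
    sample_ids: list[str]
    explained_variance: float
    convergence: dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def component_names(self) -> list[str]:
        return [f"C{r + 1}" for r in range(self.n_components)]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.component_names)

    def em_peaks(self) -> np.ndarray:
        return self.em_grid[np.argmax(self.em_loadings, axis=0)]

    def ex_peaks(self) -> np.ndarray:
        return self.ex_grid[np.argmax(self.ex_loadings, axis=0)]

    # ------------------------------------------------------------------ I/O
    def to_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.ex_loadings, index=self.ex_grid, columns=self.component_names).rename_axis(
            "wavelength_nm"
        ).to_csv(out_dir / "ex_loadings.csv")
        pd.DataFrame(self.em_loadings, index=self.em_grid, columns=self.component_names).rename_axis(
            "wavelength_nm"
        ).to_csv(out_dir / "em_loadings.csv")
        self.scores_frame().rename_axis("sample").to_csv(out_dir / "scores.csv")
        meta = {
            "n_components": self.n_components,
            "explained_variance": self.explained_variance,
            "convergence": self.convergence,
            "degenerate": self.degenerate,
        }
        (out_dir / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence coefficient (uncentered cosine) of two loadings.

    Scale-invariant, in [-1, 1]; the conventional similarity measure for
    comparing fluorescence spectra, with > 0.95 treated as a match.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("tucker congruence undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _nnls_rows(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Row-wise solve of min ||M - A Z^T||_F subject to A >= 0.

    Uses the unconstrained normal-equation solution where it is already
    feasible and falls back to an exact small NNLS (via the Cholesky factor
    of the Gram matrix) only for rows with active constraints.
    """
    G = Z.T @ Z
    ridge = 1e-12 * max(np.trace(G), 1.0)
    G = G + ridge * np.eye(G.shape[0])
    H = M @ Z
    A = np.linalg.solve(G, H.T).T
    bad = np.nonzero((A < -1e-10).any(axis=1))[0]
    if bad.size:
        L = np.linalg.cholesky(G)  # G = L L^T
        Q = L.T
        for i in bad:
            b = np.linalg.solve(L, H[i])
            A[i], _ = nnls(Q, b)
    return np.clip(A, 0.0, None)


def _reconstruct(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.einsum("ir,jr,kr->ijk", A, B, C)


def _als_single_start(
    X: np.ndarray,
    mask: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    tol: float,
    max_iter: int,
    ss_total: float,
    A: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    I, J, K = X.shape
    if A is None:
        Xc = np.where(mask, X, 0.0)
    else:
        Xc = np.where(mask, X, _reconstruct(A, B, C))
    prev_loss = np.inf
    loss = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        A = _nnls_rows(Xc.reshape(I, J * K), np.einsum("jr,kr->jkr", B, C).reshape(J * K, -1))
        B = _nnls_rows(
            Xc.transpose(1, 0, 2).reshape(J, I * K),
            np.einsum("ir,kr->ikr", A, C).reshape(I * K, -1),
        )
        C = _nnls_rows(
            Xc.transpose(2, 0, 1).reshape(K, I * J),
            np.einsum("ir,jr->ijr", A, B).reshape(I * J, -1),
        )
        Xhat = _reconstruct(A, B, C)
        loss = float(np.sum((X - Xhat)[mask] ** 2))
        # ALS with model imputation is majorization-minimization: the
        # observed-cell loss cannot increase between sweeps.
        assert loss <= prev_loss + 1e-9 * max(ss_total, 1.0), "ALS loss increased"
        Xc = np.where(mask, X, Xhat)
        if loss <= 1e-15 * ss_total:
            # Machine-precision fit (exact trilinear data): the relative
            # decrease criterion would otherwise never trigger because the
            # loss keeps shrinking geometrically toward zero.
            converged = True
            break
        if prev_loss < np.inf and (prev_loss - loss) <= tol * max(prev_loss, 1e-300):
            converged = True
            break
        prev_loss = loss
    return A, B, C, loss, it, converged


def fit_parafac(
    cube: EEMCube,
    n_components: int = 3,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2500,
    seed: int = 0,
) -> PARAFACModel:
    """Fit a non-negative PARAFAC model to a corrected EEM cube.

    The best of ``n_starts`` random initializations plus one SVD-magnitude
    start is kept. Loadings are normalized to unit Euclidean norm with the
    magnitude absorbed by the scores, and components are ordered by
    ascending emission-peak wavelength (ties broken by excitation peak).
    ``explained_variance`` is 1 - SS_residual/SS_total over non-missing
    cells. Degenerate solutions (two components with mutual spectral TCC
    > 0.98) and failure to converge in any start are flagged, not raised.
    """
    if not cube.corrected:
        raise ValueError("PARAFAC requires a corrected cube")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if cube.n_samples <= n_components:
        raise ValueError("need more samples than components")

    X = cube.intensities
    mask = np.isfinite(X)
    ss_total = float(np.sum(X[mask] ** 2))
    if ss_total == 0:
        raise ValueError("cube is identically zero")
    I, J, K = X.shape
    R = n_components
    rng = np.random.default_rng(seed)

    # SVD-magnitude start from the zero-filled unfoldings.
    X0 = np.where(mask, X, 0.0)
    inits: list[tuple[np.ndarray, np.ndarray]] = []
    try:
        Ub = np.linalg.svd(X0.transpose(1, 0, 2).reshape(J, I * K), full_matrices=False)[0]
        Uc = np.linalg.svd(X0.transpose(2, 0, 1).reshape(K, I * J), full_matrices=False)[0]
        inits.append((np.abs(Ub[:, :R]) + 1e-9, np.abs(Uc[:, :R]) + 1e-9))
    except np.linalg.LinAlgError:  # pragma: no cover - SVD rarely fails
        pass
    for _ in range(n_starts):
        inits.append((rng.random((J, R)) + 0.1, rng.random((K, R)) + 0.1))

    # Two-phase multi-start: every initialization gets a short exploratory
    # run; only the start with the lowest exploratory loss is refined to
    # full convergence. Loss is monotone within each run, so the winner of
    # the exploration is the natural candidate for refinement.
    explore_iter = min(60, max_iter)
    best = None
    for B0, C0 in inits:
        A, B, C, loss, iters, conv = _als_single_start(
            X, mask, B0.copy(), C0.copy(), tol, explore_iter, ss_total
        )
        if best is None or loss < best[3]:
            best = (A, B, C, loss, iters, conv)
    A, B, C, loss, iters, conv = best
    if not conv and max_iter > explore_iter:
        A, B, C, loss, more, conv = _als_single_start(
            X, mask, B, C, tol, max_iter - explore_iter, ss_total, A=A
        )
        iters += more
    any_converged = conv

    # Normalize loadings; push magnitude into the scores.
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    nb[nb == 0] = 1.0
    nc[nc == 0] = 1.0
    B = B / nb
    C = C / nc
    A = A * (nb * nc)

    # Order components by ascending emission peak, ties by excitation peak.
    em_peaks = cube.em_grid[np.argmax(B, axis=0)]
    ex_peaks = cube.ex_grid[np.argmax(C, axis=0)]
    order = np.lexsort((ex_peaks, em_peaks))
    A, B, C = A[:, order], B[:, order], C[:, order]

    degenerate = False
    for r in range(R):
        for s in range(r + 1, R):
            t = tucker_congruence(B[:, r], B[:, s]) * tucker_congruence(C[:, r], C[:, s])
            if t > 0.98:
                degenerate = True
    if degenerate:
        warnings.warn("degenerate PARAFAC solution: near-identical components", stacklevel=2)
    if not any_converged:
        warnings.warn("no ALS start converged within max_iter", stacklevel=2)

    return PARAFACModel(
        n_components=R,
        ex_grid=cube.ex_grid.copy(),
        em_grid=cube.em_grid.copy(),
        ex_loadings=C,
        em_loadings=B,
        scores=A,
        sample_ids=list(cube.sample_ids),
        explained_variance=1.0 - loss / ss_total,
        convergence={
            "iterations": int(iters),
            "final_loss": loss,
            "n_starts": len(inits),
            "converged": bool(any_converged),
        },
        degenerate=degenerate,
    )


# ------------------------------------------------------------- split-half


@dataclass
class SplitHalfResult:
    """Per-split matched-component congruences and the overall verdict."""

    splits: list[dict]
    threshold: float
    passed: bool


def _match_loadings(
    model_a: PARAFACModel, model_b: PARAFACModel
) -> list[tuple[int, int, float, float]]:
    """Bijectively match components of two models by maximizing summed TCC."""
    R = model_a.n_components
    tcc_ex = np.zeros((R, R))
    tcc_em = np.zeros((R, R))
    for r in range(R):
        for s in range(R):
            tcc_ex[r, s] = tucker_congruence(model_a.ex_loadings[:, r], model_b.ex_loadings[:, s])
            tcc_em[r, s] = tucker_congruence(model_a.em_loadings[:, r], model_b.em_loadings[:, s])
    rows, cols = linear_sum_assignment(-(tcc_ex + tcc_em))
    return [(int(r), int(s), float(tcc_ex[r, s]), float(tcc_em[r, s])) for r, s in zip(rows, cols)]


def split_half_validate(
    cube: EEMCube,
    n_components: int = 3,
    n_splits: int = 4,
    seed: int = 0,
    threshold: float = 0.95,
    **fit_kwargs,
) -> SplitHalfResult:
    """Split-half validation of a PARAFAC rank.

    Samples are randomly partitioned into halves ``n_splits`` times; a model
    is fitted to each half and components are matched between halves by
    maximizing summed Tucker congruence. The rank passes when every matched
    pair exceeds ``threshold`` on both excitation and emission loadings in
    every split.
    """
    if cube.n_samples < 2 * (n_components + 1):
        raise ValueError("too few samples for split-half validation")
    rng = np.random.default_rng(seed)
    splits = []
    passed = True
    for s in range(n_splits):
        perm = rng.permutation(cube.n_samples)
        half = cube.n_samples // 2
        idx_a, idx_b = perm[:half], perm[half:]
        halves = []
        for idx in (idx_a, idx_b):
            sub = EEMCube(
                sample_ids=[cube.sample_ids[i] for i in idx],
                ex_grid=cube.ex_grid,
                em_grid=cube.em_grid,
                intensities=cube.intensities[idx],
                corrected=True,
                provenance=dict(cube.provenance),
            )
            halves.append(
                fit_parafac(sub, n_components=n_components, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
            )
        pairs = _match_loadings(halves[0], halves[1])
        split_pass = all(te > threshold and tm > threshold for _, _, te, tm in pairs)
        passed = passed and split_pass
        splits.append({"pairs": pairs, "passed": split_pass})
    return SplitHalfResult(splits=splits, threshold=threshold, passed=passed)


# ------------------------------------------------------------------- Fmax


def compute_fmax(model: PARAFACModel) -> pd.DataFrame:
    """Fmax per sample and component (Raman units).

    Fmax[i, r] = score[i, r] * max(ex_loading_r) * max(em_loading_r): the
    modeled fluorescence of component r in sample i at its excitation and
    emission maxima, the conventional component quantity.
    """
    fmax = model.scores * model.ex_loadings.max(axis=0) * model.em_loadings.max(axis=0)
    return pd.DataFrame(fmax, index=model.sample_ids, columns=model.component_names)


def fmax_relative(fmax: pd.DataFrame) -> pd.DataFrame:
    """Relative abundance of each component: Fmax_r / sum_r Fmax_r."""
    totals = fmax.sum(axis=1)
    return fmax.div(totals, axis=0)


# ---------------------------------------------------------------- matching


@dataclass
class LibraryEntry:
    entry_id: str
    label: str
    ex_wavelengths: np.ndarray
    ex_loading: np.ndarray
    em_wavelengths: np.ndarray
    em_loading: np.ndarray


@dataclass
class ComponentMatch:
    component: str
    entry_id: str
    label: str
    tcc_ex: float
    tcc_em: float
    matched: bool


def default_library() -> list[LibraryEntry]:
    """Reference spectra for the three default humic-like components."""
    from ._utils import gaussian_profile
    from .eem import EX_GRID, EM_GRID
    from .synth import default_components

    entries = []
    for i, c in enumerate(default_components()):
        entries.append(
            LibraryEntry(
                entry_id=f"LIB{i + 1}",
                label=c.label,
                ex_wavelengths=EX_GRID.copy(),
                ex_loading=gaussian_profile(EX_GRID, c.ex_peak, c.ex_width),
                em_wavelengths=EM_GRID.copy(),
                em_loading=gaussian_profile(EM_GRID, c.em_peak, c.em_width),
            )
        )
    return entries


def library_to_csv(entries: list[LibraryEntry], path) -> None:
    rows = []
    for e in entries:
        for wl, v in zip(e.ex_wavelengths, e.ex_loading):
            rows.append({"entry": e.entry_id, "label": e.label, "mode": "ex", "wavelength": wl, "value": v})
        for wl, v in zip(e.em_wavelengths, e.em_loading):
            rows.append({"entry": e.entry_id, "label": e.label, "mode": "em", "wavelength": wl, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def library_from_csv(path) -> list[LibraryEntry]:
    df = pd.read_csv(path)
    entries = []
    for eid, sub in df.groupby("entry", sort=True):
        ex = sub[sub["mode"] == "ex"].sort_values("wavelength")
        em = sub[sub["mode"] == "em"].sort_values("wavelength")
        entries.append(
            LibraryEntry(
                entry_id=str(eid),
                label=str(sub["label"].iloc[0]),
                ex_wavelengths=ex["wavelength"].to_numpy(float),
                ex_loading=ex["value"].to_numpy(float),
                em_wavelengths=em["wavelength"].to_numpy(float),
                em_loading=em["value"].to_numpy(float),
            )
        )
    return entries


def match_components(
    model: PARAFACModel,
    library: list[LibraryEntry],
    threshold: float = 0.95,
) -> list[ComponentMatch]:
    """Match model components against a local reference spectral library.

    Library spectra are linearly interpolated onto the model grids (zero
    outside their support); for each component the best entry by
    min(TCC_ex, TCC_em) is reported, flagged as matched when both exceed
    ``threshold``.
    """
    if not library:
        raise ValueError("empty reference library")
    out = []
    for r, name in enumerate(model.component_names):
        best = None
        for e in library:
            ex_i = np.interp(model.ex_grid, e.ex_wavelengths, e.ex_loading, left=0.0, right=0.0)
            em_i = np.interp(model.em_grid, e.em_wavelengths, e.em_loading, left=0.0, right=0.0)
            if not ex_i.any() or not em_i.any():
                continue
            te = tucker_congruence(model.ex_loadings[:, r], ex_i)
            tm = tucker_congruence(model.em_loadings[:, r], em_i)
            score = min(te, tm)
            if best is None or score > best[0]:
                best = (score, e, te, tm)
        if best is None:
            raise ValueError("library has no support on the model grids")
        _, e, te, tm = best
        out.append(
            ComponentMatch(
                component=name,
                entry_id=e.entry_id,
                label=e.label,
                tcc_ex=te,
                tcc_em=tm,
                matched=bool(te > threshold and tm > threshold),
            )
        )
    return out
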