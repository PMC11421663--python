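"""Classical inverse solvers for the differential Beer-Lambert law.

The linear (absorption-only) model is solved in closed form with the
pseudoinverse of the scaled basis matrix; the scattering model is fit by
bounded trust-region nonlinear least squares (scipy) over the concentration
changes and the four scattering parameters (s1, b1, s2, b2).

Only the net scattering curve s2*(l/500)^-b2 - s1*(l/500)^-b1 is identifiable,
so fits are judged on the reproduced attenuation and the concentration
changes, never on individual s/b values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .basis import ChromophoreBasis
from .forward import (
    REFERENCE_WAVELENGTH_NM,
    AttenuationSpectrum,
    DeltaComposition,
    ScatteringParams,
    forward_delta_attenuation,
)

__all__ = [
    "FitResult",
    "SolveConfig",
    "ModelComparison",
    "default_bounds",
    "solve_linear",
    "solve_nonlinear",
    "solve_batch",
    "compare_models",
]

logger = logging.getLogger(__name__)

SCATTER_PARAM_NAMES = ("s1", "b1", "s2", "b2")

#: Physiologically motivated default parameter bounds. Concentration bounds
#: (mM cm^-1 under unit pathlength) cover hypoxia-scale excursions for the
#: hemoglobins and half that for the cytochrome signals; scattering weight and
#: power bounds cover the range reported for brain tissue.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "HbO2": (-0.5, 0.5),
    "HHb": (-0.5, 0.5),
    "diffCCO": (-0.25, 0.25),
    "oxCCO": (-0.25, 0.25),
    "redCCO": (-0.25, 0.25),
    "water": (-0.1, 0.1),
    "fat": (-0.1, 0.1),
    "s1": (0.0, 100.0),
    "b1": (0.0, 5.0),
    "s2": (0.0, 100.0),
    "b2": (0.0, 5.0),
}


def default_bounds(names: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Default (lo, hi) for each chromophore plus the scattering parameters.

    Chromophores without a stock entry are unbounded.
    """
    out: dict[str, tuple[float, float]] = {}
    for n in names:
        out[n] = DEFAULT_BOUNDS.get(n, (-np.inf, np.inf))
    for p in SCATTER_PARAM_NAMES:
        out[p] = DEFAULT_BOUNDS[p]
    return out


@dataclass(frozen=True)
class SolveConfig:
    """Configuration of an inverse solve.

    `warm_start=True` initialises the concentration changes of the nonlinear
    fit at the linear (pseudoinverse) solution with equal before/after
    scattering states, so its starting residual equals the linear fit's and
    the scattering fit can never end up worse (nested models). With
    `warm_start=False` the initial guess is all-zero concentrations (or
    `initial_guess` when provided).
    """

    model_variant: Literal["linear", "scattering"] = "scattering"
    bounds: Mapping[str, tuple[float, float]] | None = None
    initial_guess: Mapping[str, float] | None = None
    tolerance: float = 1e-12
    max_iterations: int = 1000
    pathlength_l: float = 1.0
    warm_start: bool = True
    bound_concentrations: bool = True
    global_search: bool = True
    exponent_grid: int = 13

    def __post_init__(self) -> None:
        if self.model_variant not in ("linear", "scattering"):
            raise ValueError(f"unknown model_variant {self.model_variant!r}")
        if self.tolerance <= 0 or self.max_iterations < 1 or self.pathlength_l <= 0:
            raise ValueError("tolerance, max_iterations and pathlength must be positive")

    def resolved_bounds(self, names: Sequence[str]) -> dict[str, tuple[float, float]]:
        out = default_bounds(names)
        if self.bounds:
            out.update({k: (float(lo), float(hi)) for k, (lo, hi) in self.bounds.items()})
        if not self.bound_concentrations:
            for n in names:
                out[n] = (-np.inf, np.inf)
        for k, (lo, hi) in out.items():
            if lo > hi:
                raise ValueError(f"bound for {k!r} has lo {lo} > hi {hi}")
        return out


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single inverse solve."""

    composition: DeltaComposition
    residual_spectrum: AttenuationSpectrum  # model minus data
    spectral_mae: float
    converged: bool
    n_iterations: int

    def delta_c_vector(self, names: Sequence[str]) -> np.ndarray:
        return self.composition.vector(tuple(names))


def _check_grid(delta_A: AttenuationSpectrum, basis: ChromophoreBasis) -> None:
    if not np.array_equal(delta_A.grid.wavelengths, basis.grid.wavelengths):
        raise ValueError("attenuation spectrum and basis are on different wavelength grids")
    if len(basis.grid) < basis.n_chromophores:
        raise ValueError(
            f"underdetermined system: {len(basis.grid)} wavelengths for "
            f"{basis.n_chromophores} chromophores"
        )


def _result(
    comp: DeltaComposition,
    delta_A: AttenuationSpectrum,
    basis: ChromophoreBasis,
    converged: bool,
    n_iterations: int,
) -> FitResult:
    model = forward_delta_attenuation(comp, basis)
    residual = AttenuationSpectrum(grid=basis.grid, delta_A=model.delta_A - delta_A.delta_A)
    return FitResult(
        composition=comp,
        residual_spectrum=residual,
        spectral_mae=float(np.mean(np.abs(residual.delta_A))),
        converged=converged,
        n_iterations=n_iterations,
    )


def solve_linear(
    delta_A: AttenuationSpectrum, basis: ChromophoreBasis, l: float = 1.0
) -> FitResult:
    """Closed-form least-squares unmixing of the absorption-only model.

    dc = pinv(-l * basis) @ dA. Rank deficiency is an error (raised at basis
    construction and re-checked here), never a silent minimum-norm solve.
    """
    _check_grid(delta_A, basis)
    design = -l * basis.matrix
    rank = np.linalg.matrix_rank(design)
    if rank < basis.n_chromophores:
        raise ValueError(f"design matrix rank {rank} < {basis.n_chromophores} chromophores")
    dc = np.linalg.pinv(design) @ delta_A.delta_A
    comp = DeltaComposition(delta_c=dict(zip(basis.names, dc.tolist())), pathlength_l=l)
    return _result(comp, delta_A, basis, converged=True, n_iterations=1)


def _pack_bounds(
    names: Sequence[str], bounds: Mapping[str, tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    keys = list(names) + list(SCATTER_PARAM_NAMES)
    lo = np.array([bounds[k][0] for k in keys], dtype=float)
    hi = np.array([bounds[k][1] for k in keys], dtype=float)
    return lo, hi


def _initial_point(
    delta_A: AttenuationSpectrum,
    basis: ChromophoreBasis,
    config: SolveConfig,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    k = basis.n_chromophores
    x0 = np.zeros(k + 4)
    # scattering params: midpoint of finite bounds, zero net change (s1=s2, b1=b2)
    for j in range(4):
        blo, bhi = lo[k + j], hi[k + j]
        x0[k + j] = 0.5 * (blo + bhi) if np.isfinite(blo) and np.isfinite(bhi) else max(blo, 0.0)
    if config.initial_guess is not None:
        for i, n in enumerate(basis.names):
            if n in config.initial_guess:
                x0[i] = config.initial_guess[n]
        for j, p in enumerate(SCATTER_PARAM_NAMES):
            if p in config.initial_guess:
                x0[k + j] = config.initial_guess[p]
    elif config.warm_start:
        x0[:k] = solve_linear(delta_A, basis, l=config.pathlength_l).delta_c_vector(basis.names)
    return np.clip(x0, lo, hi)


def _make_profiler(data, B, u, l, s_lo, s_hi):
    """Box-constrained variable-projection subproblem for fixed exponents.

    Returns ``profiled(b1, b2) -> (residual, weights)`` where the weights
    (dc, s1, s2) solve the linear subproblem under the scattering-weight
    bounds (BVLS)."""
    from scipy.optimize import lsq_linear

    k = B.shape[1]
    s_hi_eff = s_hi if np.isfinite(s_hi) else 1e6
    w_lo = np.r_[[-np.inf] * k, s_lo, s_lo]
    w_hi = np.r_[[np.inf] * k, s_hi_eff, s_hi_eff]

    def profiled(b1: float, b2: float) -> tuple[np.ndarray, np.ndarray]:
        D = np.column_stack([-l * B, l * u ** (-b1), -l * u ** (-b2)])
        res = lsq_linear(D, data, bounds=(w_lo, w_hi), method="bvls")
        return D @ res.x - data, res.x

    return profiled


def _varpro_refine(profiled, k, b1, b2, b_lo, b_hi, max_nfev=200) -> np.ndarray:
    """Refine the two exponents on the profiled residual; return the full point."""
    b_lo_eff = b_lo if np.isfinite(b_lo) else 0.0
    b_hi_eff = b_hi if np.isfinite(b_hi) else 5.0
    refine = least_squares(
        lambda b: profiled(b[0], b[1])[0],
        np.clip([b1, b2], b_lo_eff, b_hi_eff),
        bounds=([b_lo_eff, b_lo_eff], [b_hi_eff, b_hi_eff]),
        method="trf",
        ftol=1e-15,
        xtol=1e-15,
        gtol=1e-15,
        max_nfev=max_nfev,
    )
    rb1, rb2 = refine.x
    _, sol = profiled(rb1, rb2)
    return np.concatenate([sol[:k], [sol[k], rb1, sol[k + 1], rb2]])


def _profile_candidates(
    data: np.ndarray,
    B: np.ndarray,
    u: np.ndarray,
    l: float,
    b_lo: float,
    b_hi: float,
    s_lo: float,
    s_hi: float,
    n_grid: int,
    n_keep: int = 6,
) -> list[np.ndarray]:
    """Initial points from variable projection over the two scattering exponents.

    For fixed (b1, b2) the model is linear in (dc, s1, s2), so those are
    profiled out by a box-constrained least-squares solve (BVLS) with the
    scattering-weight bounds enforced, on a full (b1, b2) grid. Enforcing the
    weight bounds during profiling matters: without them, near-collinear
    exponent cells admit huge-weight representations whose clipped versions
    are useless starting points. Because near-degenerate scattering pairs
    yield several shallow basins of almost equal profiled cost, the returned
    candidates are the best cells subject to a diversity constraint (at least
    two grid steps apart in either exponent), not just the overall best.
    """
    k = B.shape[1]
    b_hi_eff = b_hi if np.isfinite(b_hi) else 5.0
    b_lo_eff = b_lo if np.isfinite(b_lo) else 0.0
    profiled = _make_profiler(data, B, u, l, s_lo, s_hi)

    bgrid = np.linspace(b_lo_eff, b_hi_eff, n_grid)
    cells: list[tuple[float, int, int, np.ndarray]] = []
    for i, b1 in enumerate(bgrid):
        for j, b2 in enumerate(bgrid):
            r, sol = profiled(b1, b2)
            cells.append((float(r @ r), i, j, sol))
    cells.sort(key=lambda c: c[0])

    kept: list[tuple[int, int]] = []
    for cost, i, j, sol in cells:
        if len(kept) >= n_keep:
            break
        if any(abs(i - pi) < 2 and abs(j - pj) < 2 for pi, pj in kept):
            continue
        kept.append((i, j))

    # refine each kept cell's exponents on the profiled residual (grid spacing
    # is too coarse for the joint polish to recover from on its own)
    candidates: list[tuple[float, np.ndarray]] = []
    for i, j in kept:
        cand = _varpro_refine(profiled, k, bgrid[i], bgrid[j], b_lo_eff, b_hi_eff, max_nfev=60)
        r, _ = profiled(cand[k + 1], cand[k + 3])
        candidates.append((float(r @ r), cand))
    candidates.sort(key=lambda c: c[0])
    return [c[1] for c in candidates]


def solve_nonlinear(
    delta_A: AttenuationSpectrum, basis: ChromophoreBasis, config: SolveConfig | None = None
) -> FitResult:
    """Bounded nonlinear least-squares fit of the scattering model.

    Jointly fits {dc_i, s1, b1, s2, b2} minimising the sum of squared
    residuals within bounds, with an analytic Jacobian. Because the
    two-power-law decomposition has many shallow local minima, the joint
    trust-region fit is started both from the linear warm start (zero net
    scattering) and, when `global_search` is on (the default), from
    variable-projection candidates that profile out everything except the two
    exponents; the lowest-cost polished solution wins. Non-convergence within
    the iteration budget yields ``converged=False``, not an exception.
    """
    config = config or SolveConfig()
    if config.model_variant != "scattering":
        raise ValueError("solve_nonlinear requires model_variant='scattering'")
    _check_grid(delta_A, basis)
    k = basis.n_chromophores
    lo, hi = _pack_bounds(basis.names, config.resolved_bounds(basis.names))

    l = config.pathlength_l
    B = basis.matrix
    u = basis.grid.wavelengths / REFERENCE_WAVELENGTH_NM
    log_u = np.log(u)
    data = delta_A.delta_A

    def residuals(x: np.ndarray) -> np.ndarray:
        dc, s1, b1, s2, b2 = x[:k], x[k], x[k + 1], x[k + 2], x[k + 3]
        model = -l * (B @ dc + s2 * u ** (-b2) - s1 * u ** (-b1))
        return model - data

    def jacobian(x: np.ndarray) -> np.ndarray:
        s1, b1, s2, b2 = x[k], x[k + 1], x[k + 2], x[k + 3]
        w1 = u ** (-b1)
        w2 = u ** (-b2)
        J = np.empty((u.size, k + 4))
        J[:, :k] = -l * B
        J[:, k] = l * w1
        J[:, k + 1] = -l * s1 * log_u * w1
        J[:, k + 2] = -l * w2
        J[:, k + 3] = l * s2 * log_u * w2
        return J

    starts = [_initial_point(delta_A, basis, config, lo, hi)]
    profiled = None
    if config.global_search:
        b_bounds = config.resolved_bounds(basis.names)
        b_lo = min(b_bounds["b1"][0], b_bounds["b2"][0])
        b_hi = max(b_bounds["b1"][1], b_bounds["b2"][1])
        s_lo = min(b_bounds["s1"][0], b_bounds["s2"][0])
        s_hi = max(b_bounds["s1"][1], b_bounds["s2"][1])
        profiled = _make_profiler(data, B, u, l, s_lo, s_hi)
        starts += [
            np.clip(c, lo, hi)
            for c in _profile_candidates(
                data, B, u, l, b_lo, b_hi, s_lo, s_hi, config.exponent_grid
            )
        ]

    # sum-of-squares at which the fit is machine-exact and polishing is moot,
    # and a spectral-MAE level far below any reported tolerance at which
    # trying further starts cannot change the outcome
    machine_floor = data.size * 1e-24
    mae_floor = 1e-9 * max(1.0, float(np.mean(np.abs(data))))

    # Candidates are ranked by spectral MAE (the reported fit metric), with
    # SSE as tie-breaker. Each start point is itself a candidate: the warm
    # start equals the linear fit with zero net scattering, so the returned
    # scattering fit can never have worse spectral MAE than the linear fit
    # (nested models) even on noisy data where the SSE and MAE optima differ.
    def _key(r: np.ndarray) -> tuple[float, float]:
        return float(np.mean(np.abs(r))), float(r @ r)

    best: tuple[tuple[float, float], np.ndarray, bool] | None = None
    total_nfev = 0
    for x0 in starts:
        key0 = _key(residuals(x0))
        if best is None or key0 < best[0]:
            best = (key0, x0, True)
        if best[0][1] <= machine_floor or best[0][0] <= mae_floor:
            break
        res = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=(lo, hi),
            method="trf",
            ftol=config.tolerance,
            xtol=config.tolerance,
            gtol=config.tolerance,
            max_nfev=config.max_iterations,
        )
        total_nfev += int(res.nfev)
        converged = bool(res.status > 0) or 2.0 * res.cost <= machine_floor
        key = _key(res.fun)
        if key < best[0]:
            best = (key, res.x, converged)
        if best[0][1] <= machine_floor or best[0][0] <= mae_floor:
            break

    assert best is not None
    if profiled is not None and best[0][0] > mae_floor:
        # the joint trust-region polish can stall in the ill-conditioned
        # valley around the optimum; a variable-projection refine of the two
        # exponents from the best point is far better conditioned there
        cand = np.clip(
            _varpro_refine(profiled, k, best[1][k + 1], best[1][k + 3], b_lo, b_hi),
            lo,
            hi,
        )
        key = _key(residuals(cand))
        if key < best[0]:
            best = (key, cand, True)

    _, x, converged = best
    comp = DeltaComposition(
        delta_c=dict(zip(basis.names, x[:k].tolist())),
        scatter_before=ScatteringParams(s=float(x[k]), b=float(x[k + 1])),
        scatter_after=ScatteringParams(s=float(x[k + 2]), b=float(x[k + 3])),
        pathlength_l=l,
    )
    return _result(comp, delta_A, basis, converged=converged, n_iterations=max(total_nfev, 1))


def solve_batch(
    spectra: Sequence[AttenuationSpectrum],
    basis: ChromophoreBasis,
    config: SolveConfig | None = None,
) -> list[FitResult]:
    """Solve each spectrum independently, preserving order.

    Each element is produced by exactly the same code path as the corresponding
    single solve; per-spectrum failures are re-raised with the batch index.
    """
    config = config or SolveConfig()
    results: list[FitResult] = []
    for i, da in enumerate(spectra):
        try:
            if config.model_variant == "linear":
                results.append(solve_linear(da, basis, l=config.pathlength_l))
            else:
                results.append(solve_nonlinear(da, basis, config))
        except Exception as exc:
            raise type(exc)(f"spectrum {i}: {exc}") from exc
    return results


@dataclass(frozen=True)
class ModelComparison:
    """Paired linear/scattering fits of one spectrum and their relative improvement.

    `r = (MAE_scatter - MAE_linear) / MAE_linear`; negative r means the
    scattering model fits better. When the linear fit's MAE is already at the
    numerical noise floor (<= degenerate_tol) the ratio is a 0/0 limit: r is
    reported as 0 with `degenerate=True`.
    """

    linear: FitResult
    scattering: FitResult
    r: float
    degenerate: bool = False

    @property
    def improvement(self) -> float:
        """|r| as a positive improvement fraction (sign-free convention)."""
        return abs(self.r)


def compare_models(
    delta_A: AttenuationSpectrum,
    basis: ChromophoreBasis,
    config: SolveConfig | None = None,
    degenerate_tol: float = 1e-12,
) -> ModelComparison:
    """Fit both model variants and report the relative spectral-fit improvement.

    The linear fit is the unconstrained pseudoinverse solution, so for the two
    fits to be strictly nested (scattering never worse) the scattering fit is
    run without concentration bounds here; the scattering parameters keep
    their bounds, which only add degrees of freedom beyond the linear model.
    """
    config = config or SolveConfig()
    lin = solve_linear(delta_A, basis, l=config.pathlength_l)
    scat = solve_nonlinear(
        delta_A,
        basis,
        replace(config, model_variant="scattering", bound_concentrations=False),
    )
    if lin.spectral_mae <= degenerate_tol:
        return ModelComparison(linear=lin, scattering=scat, r=0.0, degenerate=True)
    r = (scat.spectral_mae - lin.spectral_mae) / lin.spectral_mae
    return ModelComparison(linear=lin, scattering=scat, r=float(r), degenerate=False)
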