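"""Inference timing benchmark: classical solvers vs the trained surrogate.

Times per-spectrum inference for the linear pseudoinverse solve, the bounded
nonlinear scattering solve (with and without the global exponent search), and
a trained MLP surrogate, on the stock 244-wavelength near-infrared grid.
Prints a table; asserts nothing — timings are hardware-dependent.

Usage::

    python scripts/benchmark_inference.py [--n 200] [--seed 0]
"""

from __future__ import annotations

import argparse
import time

import numpy as np

from blunmix.datasets import TrainingSet, sample_strategy_a
from blunmix.presets import BNIRS_CHROMOPHORES, bnirs_grid, sampling_ranges, synthetic_basis
from blunmix.solvers import SolveConfig, solve_linear, solve_nonlinear
from blunmix.surrogate import SURROGATE_PRESETS, train


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=200, help="spectra per timed method")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    basis = synthetic_basis(BNIRS_CHROMOPHORES, bnirs_grid())
    ranges = sampling_ranges(BNIRS_CHROMOPHORES, model_variant="scattering")
    ts = sample_strategy_a(ranges, basis, n=args.n, model_variant="scattering", seed=args.seed)
    spectra = ts.spectra()

    print(f"benchmark: {args.n} spectra, {len(basis.grid)} wavelengths, "
          f"{basis.n_chromophores} chromophores")
    rows = []

    t0 = time.perf_counter()
    for s in spectra:
        solve_linear(s, basis)
    rows.append(("linear pseudoinverse", (time.perf_counter() - t0) / args.n))

    cfg_local = SolveConfig(model_variant="scattering", global_search=False)
    t0 = time.perf_counter()
    for s in spectra:
        solve_nonlinear(s, basis, cfg_local)
    rows.append(("nonlinear, local (warm start only)", (time.perf_counter() - t0) / args.n))

    n_global = min(args.n, 25)  # the global search is the slow path
    cfg_global = SolveConfig(model_variant="scattering")
    t0 = time.perf_counter()
    for s in spectra[:n_global]:
        solve_nonlinear(s, basis, cfg_global)
    rows.append(("nonlinear, global exponent search", (time.perf_counter() - t0) / n_global))

    train_n = max(2000, args.n)
    tr = sample_strategy_a(ranges, basis, n=train_n, model_variant="scattering",
                           seed=args.seed + 1)
    va_raw = sample_strategy_a(ranges, basis, n=train_n // 5, model_variant="scattering",
                               seed=args.seed + 2)
    va = TrainingSet(inputs=va_raw.inputs, targets=va_raw.targets, grid=basis.grid,
                     names=basis.names, provenance="strategy_a",
                     normalization=tr.normalization)
    model, _ = train(tr, va, SURROGATE_PRESETS["bnirs-scattering-a"])

    batch = np.vstack([s.delta_A for s in spectra])
    t0 = time.perf_counter()
    model.predict_array(batch)
    rows.append(("MLP surrogate (batched)", (time.perf_counter() - t0) / args.n))

    t0 = time.perf_counter()
    for s in spectra:
        model.predict_array(s.delta_A[None, :])
    rows.append(("MLP surrogate (one at a time)", (time.perf_counter() - t0) / args.n))

    width = max(len(r[0]) for r in rows)
    print(f"\n{'method':<{width}}  per-spectrum time")
    for name, dt in rows:
        print(f"{name:<{width}}  {dt * 1e3:10.3f} ms")
    base = rows[2][1]
    print(f"\nspeedup of batched surrogate over global nonlinear solve: "
          f"{base / rows[3][1]:,.0f}x")


if __name__ == "__main__":
    main()
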