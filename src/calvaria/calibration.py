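"""Computational-vs-experimental strain comparison and modulus calibration.

The FE model's per-suture von Mises strains are compared with experimental
estimates via the magnitude of the percentage difference (experimental
denominator), Lin's concordance correlation coefficient, and an ordinary
least-squares best-fit line with R².  Bone Young's modulus is calibrated
by sweeping a grid (default log-spaced 10–7000 MPa) and selecting the
argmin of the mean |percentage difference| across sutures.

Because the isotropic stiffness is linear in E at fixed ν, the sweep
assembles each region's unit-modulus stiffness once and recombines per
grid point — one factorization per modulus, no re-assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fem
from .meshing import TetMesh


# --------------------------------------------------------------------------
# elementary statistics
# --------------------------------------------------------------------------

def percent_difference(comp, exp):
    """100·|comp − exp| / exp (experimental denominator).  exp must be > 0."""
    comp = np.asarray(comp, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if (exp <= 0).any():
        raise ValueError("experimental strain must be > 0 for a percentage difference")
    out = 100.0 * np.abs(comp - exp) / exp
    return float(out) if out.ndim == 0 else out


def lin_ccc(x, y, moments: str = "population") -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), population (1/n) moments by
    default (``moments='sample'`` uses 1/(n−1)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    ddof = 0 if moments == "population" else 1
    sxy = np.cov(x, y, ddof=ddof)[0, 1]
    sx2, sy2 = np.var(x, ddof=ddof), np.var(y, ddof=ddof)
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0  # identical constant vectors: perfect agreement
    return float(2.0 * sxy / denom)


def fit_line(x, y) -> tuple[float, float, float]:
    """OLS best-fit line: (slope, intercept, R² = 1 − SS_res/SS_tot)."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.var(x) == 0:
        raise ValueError("var(x) = 0: best-fit line undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def compare(comp, exp, exclude: list[int] | None = None) -> dict:
    """CCC, best-fit line and R² over aligned per-suture strain pairs.

    ``exclude`` drops pair indices (outlier sutures) and reports the
    recomputed values alongside the full ones.
    """
    comp = np.asarray(comp, dtype=float)
    exp = np.asarray(exp, dtype=float)
    slope, intercept, r2 = fit_line(exp, comp)
    out = {
        "ccc": lin_ccc(exp, comp),
        "slope": slope,
        "intercept": intercept,
        "r2": r2,
        "n": int(comp.size),
    }
    if exclude:
        keep = np.setdiff1d(np.arange(comp.size), np.asarray(exclude))
        if keep.size < 2:
            raise ValueError("fewer than 2 pairs after exclusion")
        s, i, r = fit_line(exp[keep], comp[keep])
        out.update(
            ccc_excluded=lin_ccc(exp[keep], comp[keep]),
            slope_excluded=s,
            intercept_excluded=i,
            r2_excluded=r,
            n_excluded=int(keep.size),
        )
    return out


# --------------------------------------------------------------------------
# modulus sweep
# --------------------------------------------------------------------------

def default_grid(lo: float = 10.0, hi: float = 7000.0, n: int = 25) -> np.ndarray:
    """Log-spaced bone-modulus grid in MPa spanning the sweep range."""
    return np.geomspace(lo, hi, n)


@dataclass
class CalibrationResult:
    """Sweep curves, per-suture percentage differences and the optimum."""

    grid: np.ndarray
    curves: pd.DataFrame            # strain per (modulus × suture)
    pct_diff: pd.DataFrame          # |% difference| per (modulus × suture)
    mean_pct_diff: np.ndarray
    best_modulus: float
    failed: list[float] = field(default_factory=list)
    comparison_at_best: dict | None = None


def sweep_suture_strain(
    mesh: TetMesh,
    tet_pair_index: np.ndarray,
    pair_names: dict,
    load_case: fem.LoadCase,
    grid,
    fixed: fem.MaterialSet | None = None,
) -> pd.DataFrame:
    """Per-suture volume-averaged von Mises strain at each grid modulus.

    ``fixed`` carries the non-bone moduli (default: adjusted set, brain
    3 Pa / suture 30 kPa, ν = 0.3); bone (and constraint patches) take the
    grid value.  Rows: modulus MPa; columns: suture names.
    """
    fixed = fixed or fem.MaterialSet.adjusted()
    parts = fem.region_stiffnesses(mesh, fixed.poisson)
    vols = mesh.volumes()
    rows = {}
    for e_bone in np.asarray(grid, dtype=float):
        mats = fem.MaterialSet(dict(fixed.young, bone=float(e_bone)), fixed.poisson)
        K = fem.combine_stiffness(parts, mesh, mats)
        system = fem.system_from_stiffness(mesh, K)
        fem.apply_load_case(system, load_case)
        try:
            res = fem.solve(system)
        except RuntimeError:
            rows[float(e_bone)] = None
            continue
        row = {}
        for pair, idx in sorted(pair_names.items()):
            sel = tet_pair_index == idx
            if not sel.any():
                continue
            w = vols[sel]
            row[str(pair)] = float(res.von_mises[sel] @ (w / w.sum()))
        rows[float(e_bone)] = row
    ok = {e: r for e, r in rows.items() if r is not None}
    df = pd.DataFrame.from_dict(ok, orient="index").sort_index()
    df.attrs["failed"] = [e for e, r in rows.items() if r is None]
    return df


def calibrate(curves: pd.DataFrame, exp: dict | pd.Series) -> CalibrationResult:
    """Select the modulus minimizing the mean |percentage difference|.

    ``curves`` as from :func:`sweep_suture_strain`; ``exp`` maps suture
    name → experimental von Mises strain.  The mean objective is the
    unweighted mean of the per-suture curves; both are retained.
    """
    exp = pd.Series(exp)
    common = [c for c in curves.columns if c in exp.index]
    if not common:
        raise ValueError("no sutures shared between curves and experiment")
    pct = pd.DataFrame(
        {c: percent_difference(curves[c].to_numpy(), exp[c]) for c in common},
        index=curves.index,
    )
    mean_curve = pct.mean(axis=1).to_numpy()
    best = float(pct.index[int(np.argmin(mean_curve))])
    comp_at_best = curves.loc[best, common].to_numpy()
    comparison = (
        compare(comp_at_best, exp[common].to_numpy()) if len(common) >= 2 else None
    )
    return CalibrationResult(
        grid=curves.index.to_numpy(),
        curves=curves[common],
        pct_diff=pct,
        mean_pct_diff=mean_curve,
        best_modulus=best,
        failed=list(curves.attrs.get("failed", [])),
        comparison_at_best=comparison,
    )


def sweep_modulus(
    mesh: TetMesh,
    tet_pair_index: np.ndarray,
    pair_names: dict,
    load_case: fem.LoadCase,
    exp: dict | pd.Series,
    grid=None,
    fixed: fem.MaterialSet | None = None,
) -> CalibrationResult:
    """Full inverse calibration: FE sweep then argmin selection."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    curves = sweep_suture_strain(mesh, tet_pair_index, pair_names, load_case, grid, fixed)
    return calibrate(curves, exp)
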