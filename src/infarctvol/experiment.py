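"""Lesion-recovery simulation study.

Runs the full pipeline over a grid of true lesion volumes x density
reductions x correction backends on the synthetic head phantom, and reports
recovery ratios (measured / true, percent) and the Pearson correlation of
measured against true volume per backend and density reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iic import BACKENDS, IICParams
from .model import CTInfarctModel
from .phantom import LesionSpec, PhantomSpec, default_lesion_center, insert_lesion, make_head_phantom

DEFAULT_VOLUMES_CC = (122.0, 45.0, 17.0)
DEFAULT_REDUCTIONS = (0.30, 0.20, 0.10, 0.05)


@dataclass
class GridSpec:
    """The recovery-study grid: lesion volumes x density reductions."""

    volumes_cc: tuple = DEFAULT_VOLUMES_CC
    reductions: tuple = DEFAULT_REDUCTIONS
    backends: tuple = BACKENDS
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    replicates: int = 1
    seed: int = 0
    side: str = "right"
    lesion_offset_mm: float = 35.0
    iic_params: IICParams = field(default_factory=IICParams)

    def __post_init__(self) -> None:
        if not self.volumes_cc or not self.reductions or not self.backends:
            raise ValueError("volumes_cc, reductions and backends must be nonempty")
        if any(not (0 < f <= 0.5) for f in self.reductions):
            raise ValueError("reductions must lie in (0, 0.5]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class GridResult:
    """Per-cell measurements and per-(backend, reduction) correlations."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    failures: list = field(default_factory=list)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Computed from the standard formula
    ``r = sum(dx*dy) / sqrt(sum(dx^2) * sum(dy^2))`` with ``dx = x - mean(x)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in x or y")
    return float(np.dot(dx, dy) / np.sqrt(sxx * syy))


def _cell_seed(base_seed: int, cell_index: int) -> int:
    # stated rule: base seed + cell index, kept within the 32-bit seed range
    return (base_seed + cell_index) % (2**31)


def run_grid(spec: GridSpec) -> GridResult:
    """Run the recovery study.

    One phantom per (volume, reduction, replicate) cell, with a single
    right-sided (or ``spec.side``) spherical lesion; both backends run on
    the same phantom.  Per-cell phantoms use the deterministic seed
    ``spec.seed + cell_index`` so cells are independent yet reproducible.
    """
    rows = []
    failures = []
    cell_index = 0
    for v_cc in spec.volumes_cc:
        for f in spec.reductions:
            for rep in range(spec.replicates):
                seed = _cell_seed(spec.seed, cell_index)
                cell_index += 1
                try:
                    pspec = replace(spec.phantom, seed=seed)
                    truth = make_head_phantom(pspec)
                    lesion = LesionSpec(
                        shape="sphere",
                        center=default_lesion_center(
                            pspec, spec.side, spec.lesion_offset_mm
                        ),
                        target_volume_cc=v_cc,
                        density_reduction=f,
                        side=spec.side,
                    )
                    truth = insert_lesion(truth, lesion)
                    model = CTInfarctModel(truth.image, iic_params=spec.iic_params)
                except Exception as exc:  # phantom-level failure hits all backends
                    for backend in spec.backends:
                        failures.append((backend, v_cc, f, rep, repr(exc)))
                    continue
                for backend in spec.backends:
                    try:
                        res = model.fit(backend=backend, side=spec.side)
                        measured = res.infarct_cc
                    except Exception as exc:
                        failures.append((backend, v_cc, f, rep, repr(exc)))
                        continue
                    rows.append(
                        {
                            "backend": backend,
                            "true_cc": truth.lesion_volume_true,
                            "nominal_cc": v_cc,
                            "reduction": f,
                            "replicate": rep,
                            "measured_cc": measured,
                            "ratio_pct": 100.0 * measured / truth.lesion_volume_true,
                            "seed": seed,
                        }
                    )
    if not rows:
        raise RuntimeError(f"all grid cells failed: {failures}")
    table = pd.DataFrame(rows)

    corr_rows = []
    for backend in spec.backends:
        for f in spec.reductions:
            sub = table[(table.backend == backend) & (table.reduction == f)]
            if sub.nominal_cc.nunique() >= 3:
                r = pearson_r(sub.true_cc.to_numpy(), sub.measured_cc.to_numpy())
                corr_rows.append({"backend": backend, "reduction": f, "pearson_r": r})
    correlations = pd.DataFrame(corr_rows)
    return GridResult(table=table, correlations=correlations, failures=failures)


def summarize_ratios(result: GridResult) -> dict[str, pd.DataFrame]:
    """Recovery-ratio tables (percent), one per backend.

    Rows are true volumes in descending order, columns density reductions in
    descending order, mirroring the recovery study's presentation.
    """
    out = {}
    table = result.table
    for backend in table.backend.unique():
        sub = table[table.backend == backend]
        piv = sub.pivot_table(
            index="nominal_cc", columns="reduction", values="ratio_pct", aggfunc="mean"
        )
        piv = piv.reindex(sorted(piv.index, reverse=True))
        piv = piv[sorted(piv.columns, reverse=True)]
        piv.index = [f"{v:g}cc" for v in piv.index]
        piv.columns = [f"{100 * f:g}%" for f in piv.columns]
        out[backend] = piv
    return out


def write_outputs(result: GridResult, out_dir, plot: bool = False) -> None:
    """Write grid_results.csv, per-backend ratio tables and correlations."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "grid_results.csv", index=False)
    for backend, piv in summarize_ratios(result).items():
        piv.to_csv(out / f"ratio_table_{backend}.csv")
    result.correlations.to_csv(out / "correlations.csv", index=False)
    if plot:
        _plot_recovery(result, out / "recovery_scatter.png")


def _plot_recovery(result: GridResult, path) -> None:
    """Measured vs true volume scatter, one panel per backend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    backends = list(result.table.backend.unique())
    fig, axes = plt.subplots(1, len(backends), figsize=(5 * len(backends), 4), squeeze=False)
    for ax, backend in zip(axes[0], backends):
        sub = result.table[result.table.backend == backend]
        for f in sorted(sub.reduction.unique(), reverse=True):
            s = sub[sub.reduction == f].sort_values("true_cc")
            ax.plot(s.true_cc, s.measured_cc, "o-", label=f"{100 * f:g}%")
        lim = max(sub.true_cc.max(), sub.measured_cc.max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("true volume (cc)")
        ax.set_ylabel("measured volume (cc)")
        ax.set_title(backend)
        ax.legend(title="density reduction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
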