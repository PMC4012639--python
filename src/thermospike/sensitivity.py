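"""Grid-based global sensitivity analysis and dimensional stacking.

The impact of a parameter on an observable is the median of all
differences between neighboring grid points along that parameter's axis
(ascending order, value(k+1) - value(k)), taken across every combination
of the other parameters — an elementary-effects design on the full
factorial grid.  Impacts are normalized so their absolute values sum to
one; 25th/75th percentiles of the difference distribution serve as error
bars, and an impact is reliable iff both percentiles share its sign.

Dimensional stacking maps the full grid onto a single 2D image by
recursively nesting axes, highest-impact parameters outermost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sweep import PARAM_ORDER, Q10Grid, SweepTable

__all__ = [
    "ImpactTable",
    "StackImage",
    "impact_scores",
    "impact_scores_from_array",
    "dimensional_stack",
    "stack_from_array",
]


@dataclass
class ImpactTable:
    """Per-parameter impact scores for one observable."""

    observable: str
    params: tuple[str, ...]
    impacts: np.ndarray          # signed, |impacts| sums to 1 (unless degenerate)
    q25: np.ndarray              # percentiles on the same normalized scale
    q75: np.ndarray
    reliable: np.ndarray         # bool
    raw_medians: np.ndarray
    dropped_fraction: float = 0.0
    degenerate: bool = False     # all raw medians zero: no normalization

    def ranking(self) -> list[int]:
        """Parameter indices sorted by |impact| descending; ties broken by
        the fixed parameter ordering."""
        return sorted(range(len(self.params)),
                      key=lambda k: (-abs(self.impacts[k]), k))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "param": self.params,
            "impact": self.impacts,
            "q25": self.q25,
            "q75": self.q75,
            "reliable": self.reliable,
            "raw_median": self.raw_medians,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sign(x: float) -> int:
    return int(x > 0) - int(x < 0)


def impact_scores_from_array(
    values: np.ndarray,
    param_names: Sequence[str] | None = None,
    observable: str = "observable",
) -> ImpactTable:
    """Impact scores for an observable given on a full factorial grid.

    ``values`` is the N-dimensional array of the observable (one axis per
    parameter, levels in ascending parameter order).  NaN entries drop
    every difference they participate in; the dropped fraction is
    reported.
    """
    values = np.asarray(values, dtype=float)
    ndim = values.ndim
    if ndim < 1:
        raise ValueError("need at least one parameter axis")
    if any(s < 2 for s in values.shape):
        raise ValueError("each parameter needs >= 2 grid steps")
    if param_names is None:
        param_names = tuple(f"p{k}" for k in range(ndim))
    if len(param_names) != ndim:
        raise ValueError("one name per grid axis required")

    medians = np.empty(ndim)
    q25 = np.empty(ndim)
    q75 = np.empty(ndim)
    n_total = 0
    n_dropped = 0
    for k in range(ndim):
        diffs = np.diff(values, axis=k).ravel()
        n_total += diffs.size
        good = diffs[np.isfinite(diffs)]
        n_dropped += diffs.size - good.size
        if good.size == 0:
            medians[k] = q25[k] = q75[k] = np.nan
            continue
        medians[k] = np.median(good)
        q25[k], q75[k] = np.percentile(good, [25, 75])

    norm = np.nansum(np.abs(medians))
    degenerate = not norm > 0
    scale = 1.0 if degenerate else 1.0 / norm
    impacts = medians * scale
    reliable = np.array([
        np.isfinite(medians[k])
        and _sign(q25[k]) == _sign(medians[k]) == _sign(q75[k])
        for k in range(ndim)
    ])
    return ImpactTable(
        observable=observable,
        params=tuple(param_names),
        impacts=impacts,
        q25=q25 * scale,
        q75=q75 * scale,
        reliable=reliable,
        raw_medians=medians,
        dropped_fraction=n_dropped / n_total if n_total else 0.0,
        degenerate=degenerate,
    )


def _grid_array(sweep: SweepTable, observable: str) -> np.ndarray:
    table = sweep.table
    if observable not in table.columns:
        raise KeyError(f"unknown observable {observable!r}")
    shape = sweep.grid.shape
    size = int(np.prod(shape))
    if len(table) != size or set(table["index"]) != set(range(size)):
        raise ValueError("impact scores require a complete factorial sweep")
    flat = np.full(size, np.nan)
    flat[table["index"].to_numpy()] = table[observable].to_numpy()
    return flat.reshape(shape)


def impact_scores(sweep: SweepTable, observable: str) -> ImpactTable:
    """Impact scores of ``observable`` over a complete factorial sweep."""
    arr = _grid_array(sweep, observable)
    return impact_scores_from_array(arr, PARAM_ORDER, observable)


# ---------------------------------------------------------------------------
# dimensional stacking
# ---------------------------------------------------------------------------

@dataclass
class StackImage:
    """2D dimensional-stacking image of a gridded observable.

    ``order`` lists parameter indices outermost-first; even positions go
    to the horizontal axis, odd positions to the vertical axis.
    """

    image: np.ndarray
    order: tuple[int, ...]
    param_names: tuple[str, ...]
    shape: tuple[int, ...]           # grid steps per parameter

    @property
    def x_params(self) -> tuple[int, ...]:
        return self.order[0::2]

    @property
    def y_params(self) -> tuple[int, ...]:
        return self.order[1::2]

    def coords_to_pixel(self, coords: Sequence[int]) -> tuple[int, int]:
        """Grid coordinates (one index per parameter) -> (row, col)."""
        col = 0
        for p in self.x_params:
            col = col * self.shape[p] + coords[p]
        row = 0
        for p in self.y_params:
            row = row * self.shape[p] + coords[p]
        return row, col

    def pixel_to_coords(self, row: int, col: int) -> tuple[int, ...]:
        coords = [0] * len(self.shape)
        for p in reversed(self.x_params):
            coords[p] = col % self.shape[p]
            col //= self.shape[p]
        for p in reversed(self.y_params):
            coords[p] = row % self.shape[p]
            row //= self.shape[p]
        return tuple(coords)

    def axis_legend(self) -> dict[str, list[str]]:
        return {
            "x": [self.param_names[p] for p in self.x_params],
            "y": [self.param_names[p] for p in self.y_params],
        }

    def save_array(self, path: str | Path) -> None:
        np.savetxt(path, self.image)

    def render(self, path: str | Path, cmap: str = "viridis") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 5))
        im = ax.imshow(self.image, origin="lower", aspect="auto", cmap=cmap,
                       interpolation="nearest")
        legend = self.axis_legend()
        ax.set_xlabel(" > ".join(legend["x"]) + "  (outer > inner)")
        ax.set_ylabel(" > ".join(legend["y"]) + "  (outer > inner)")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def stack_from_array(
    values: np.ndarray,
    order: Sequence[int],
    param_names: Sequence[str] | None = None,
) -> StackImage:
    """Stack an N-dimensional gridded observable into a 2D image.

    ``order`` lists parameter indices outermost-first; axis assignment
    alternates starting with the horizontal image axis.
    """
    values = np.asarray(values, dtype=float)
    order = tuple(int(k) for k in order)
    if sorted(order) != list(range(values.ndim)):
        raise ValueError("order must be a permutation of the parameter indices")
    if param_names is None:
        param_names = tuple(f"p{k}" for k in range(values.ndim))
    img = StackImage(
        image=np.empty((1, 1)),
        order=order,
        param_names=tuple(param_names),
        shape=values.shape,
    )
    width = int(np.prod([values.shape[p] for p in img.x_params])) or 1
    height = int(np.prod([values.shape[p] for p in img.y_params])) or 1
    # permute grid axes to (y outer..inner, x outer..inner) then reshape
    perm = tuple(img.y_params) + tuple(img.x_params)
    img.image = np.transpose(values, perm).reshape(height, width)
    return img


def dimensional_stack(
    sweep: SweepTable,
    observable: str,
    order: str | Sequence[int] = "by_impact",
    impacts: ImpactTable | None = None,
) -> StackImage:
    """Dimensional-stacking image of a sweep observable.

    ``order="by_impact"`` ranks parameters by |impact| (computing the
    impact table if not supplied); an explicit list of parameter indices
    or names is honored as-is.
    """
    arr = _grid_array(sweep, observable)
    if isinstance(order, str):
        if order != "by_impact":
            raise ValueError("order must be 'by_impact' or an explicit sequence")
        if impacts is None:
            impacts = impact_scores(sweep, observable)
        order_idx: Sequence[int] = impacts.ranking()
    else:
        order_idx = [
            PARAM_ORDER.index(o) if isinstance(o, str) else int(o) for o in order
        ]
        if sorted(order_idx) != list(range(len(PARAM_ORDER))):
            raise ValueError("order must cover each grid parameter exactly once")
    return stack_from_array(arr, order_idx, PARAM_ORDER)
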