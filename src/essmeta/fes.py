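"""Reweighted-histogram free-energy surfaces and minima detection.

Biased frames are Boltzmann-reweighted with w ∝ exp(+V(s)/kBT) using the
final metadynamics bias (a time-dependent-offset variant is available);
free energies over auxiliary descriptors follow from the weighted
histogram, F = −kBT ln ρ, shifted so the sampled minimum is zero.  Well
depths are measured by topographic persistence: the depth of a minimum is
the height of the lowest saddle separating it from any deeper minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import KB
from .metad import HillsLog, bias_value_and_gradient


@dataclass
class FESProfile:
    """Gridded free energy (kJ/mol) over one or two descriptor axes.

    axes: list of (name, bin-center array); values: kJ/mol, min over
    sampled cells exactly 0; mask: True where sampled."""

    axes: list[tuple[str, np.ndarray]]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.mask.any():
            self.values = self.values - self.values[self.mask].min()

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (axis columns + free_energy + sampled flag)."""
        grids = np.meshgrid(*[c for _, c in self.axes], indexing="ij")
        data = {name: g.ravel() for (name, _), g in zip(self.axes, grids)}
        data["free_energy"] = self.values.ravel()
        data["sampled"] = self.mask.ravel()
        return pd.DataFrame(data)

    def write(self, path) -> None:
        """Gridded text table (axis columns + free_energy + sampled flag),
        with the ``#!`` header convention so plotting tools can skip it."""
        from .io import write_table

        df = self.to_frame()
        rows = df.to_numpy(dtype=float)  # sampled flag → 0/1
        rows[:, -2] = np.where(df["sampled"], rows[:, -2], np.nan)
        write_table(path, list(df.columns), rows)


@dataclass
class Minimum:
    location: tuple[float, ...]
    value: float   # kJ/mol above the global sampled minimum
    depth: float   # kJ/mol below the lowest separating saddle


@dataclass
class MinimaReport:
    minima: list[Minimum]

    def __len__(self) -> int:
        return len(self.minima)

    def __iter__(self):
        return iter(self.minima)

    def __getitem__(self, i) -> Minimum:
        return self.minima[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**{f"axis{k}": x for k, x in enumerate(m.location)},
             "value": m.value, "depth": m.depth}
            for m in self.minima
        ]
        return pd.DataFrame(rows)


def frame_weights(cv_values: np.ndarray, times: np.ndarray, hills: HillsLog,
                  temperature: float, scheme: str = "final") -> np.ndarray:
    """Normalized reweighting weights for biased frames.

    scheme="final": w_i ∝ exp(+V_final(s_i)/kBT) (default).
    scheme="running": Tiwary–Parrinello style time-dependent offset,
    w_i ∝ exp(+(V(s_i, t_i) − c(t_i))/kBT) with
    c(t) = −kBT·ln⟨exp(−V(s, t)/kBT)⟩_grid + const; both schemes agree on
    converged runs.
    """
    cv_values = np.asarray(cv_values, dtype=float)
    times = np.asarray(times, dtype=float)
    if cv_values.shape != times.shape:
        raise ValueError("cv_values and times must have equal length")
    if len(hills) == 0:
        return np.full(cv_values.size, 1.0 / cv_values.size)
    t_hi = hills.times.max() + np.diff(np.sort(hills.times)).max() if len(hills) > 1 \
        else hills.times.max()
    if np.any(times < 0) or np.any(times > t_hi + 1e-9):
        raise ValueError("frame times lie outside the hills time span")
    kT = KB * temperature

    if scheme == "final":
        v, _ = bias_value_and_gradient(hills, cv_values)
        log_w = v / kT
    elif scheme == "running":
        # V(s_i, t_i) with the bias truncated at each frame's time and the
        # well-tempered offset
        #   c(t) = kBT·ln( ∫e^{γ/(γ−1)·V/kBT} ds / ∫e^{V/((γ−1)kBT)} ds ),
        # maintained on a dense grid updated incrementally per hill
        span = cv_values.max() - cv_values.min()
        pad = 0.02 * span + float(hills.sigmas.max())
        grid = np.linspace(cv_values.min() - pad, cv_values.max() + pad, 1024)
        order = np.argsort(times, kind="stable")
        log_w = np.empty_like(cv_values)
        h_times = hills.times
        counts = np.searchsorted(h_times, times[order], side="right")
        gamma = hills.bias_factor
        g_num = gamma / (gamma - 1.0)
        g_den = 1.0 / (gamma - 1.0)
        vg = np.zeros(grid.size)
        added = 0
        c_over_kt = 0.0
        pos = 0
        for tcut in np.unique(counts):
            while added < tcut:
                z = (grid - hills.centers[added]) / hills.sigmas[added]
                vg += hills.heights[added] * np.exp(-0.5 * z * z)
                added += 1
            if added > 0:
                vmax = vg.max()
                num = np.log(np.mean(np.exp(g_num * (vg - vmax) / kT)))
                den = np.log(np.mean(np.exp(g_den * (vg - vmax) / kT)))
                c_over_kt = num - den + (g_num - g_den) * vmax / kT
            sub = order[pos:pos + int(np.count_nonzero(counts == tcut))]
            pos += sub.size
            v_i = np.interp(cv_values[sub], grid, vg)
            log_w[sub] = v_i / kT - c_over_kt
    else:
        raise ValueError(f"unknown reweighting scheme {scheme!r}")

    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


def weighted_fes(aux: np.ndarray, weights: np.ndarray,
                 temperature: float, bins: int | tuple[int, ...] = 100,
                 axis_names: tuple[str, ...] | None = None,
                 range_pad: float = 0.02) -> FESProfile:
    """F = −kBT·ln(weighted histogram) over 1 or 2 descriptor columns.

    The histogram range is the sampled range padded by ``range_pad``;
    never-sampled bins are masked.  The sampled minimum is shifted to 0.
    """
    aux = np.asarray(aux, dtype=float)
    if aux.ndim == 1:
        aux = aux[:, None]
    weights = np.asarray(weights, dtype=float)
    if aux.shape[0] != weights.shape[0]:
        raise ValueError("aux and weights must have equal length")
    ndim = aux.shape[1]
    if ndim not in (1, 2):
        raise ValueError("aux must have 1 or 2 columns")
    if isinstance(bins, int):
        bins = (bins,) * ndim
    if axis_names is None:
        axis_names = ("x", "y")[:ndim]

    ranges = []
    for d in range(ndim):
        lo, hi = aux[:, d].min(), aux[:, d].max()
        pad = range_pad * (hi - lo) if hi > lo else max(1e-9, abs(lo) * 1e-6)
        ranges.append((lo - pad, hi + pad))

    hist, edges = np.histogramdd(aux, bins=bins, range=ranges, weights=weights)
    if np.count_nonzero(hist) == 1 and np.prod(bins) > 1:
        import warnings
        warnings.warn("all weight fell into a single bin", RuntimeWarning)
    mask = hist > 0
    values = np.full(hist.shape, np.nan)
    kT = KB * temperature
    values[mask] = -kT * np.log(hist[mask])
    centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
    axes = [(axis_names[d], centers[d]) for d in range(ndim)]
    values[~mask] = np.nan
    prof = FESProfile(axes=axes, values=np.where(mask, values, np.inf),
                      mask=mask)
    prof.values[~mask] = np.inf
    return prof


def _masked_smooth(values: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores unsampled cells (mask-normalized)."""
    v = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter(v, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = np.full(values.shape, np.inf)
    good = den > 1e-12
    out[good & mask] = num[good & mask] / den[good & mask]
    return out


def find_minima(fes: FESProfile, min_depth: float = 2.0,
                smooth_sigma: float = 1.0,
                max_value: float = np.inf) -> MinimaReport:
    """Local minima of a (smoothed) FES with persistence-based depths.

    A minimum's depth is the free energy of the lowest saddle separating
    it from any deeper minimum, minus its own value (for the global
    minimum: the saddle at which the last competing minimum merges).
    Minima shallower than ``min_depth``, or lying more than ``max_value``
    above the global minimum (sampling-starved tail regions), are
    suppressed; results sorted by value.
    """
    if fes.mask.sum() < 3 ** fes.ndim:
        raise ValueError("need at least 3 sampled cells per axis")
    f = _masked_smooth(fes.values, fes.mask, smooth_sigma) if smooth_sigma > 0 \
        else np.where(fes.mask, fes.values, np.inf)
    f = f - f[fes.mask].min()

    flat = f.ravel()
    shape = f.shape
    order = np.argsort(flat, kind="stable")
    # union-find over cells in ascending free energy; a cell that joins two
    # distinct basins is their merge saddle (topographic persistence)
    parent = np.full(flat.size, -1, dtype=np.int64)
    basin_min: dict[int, int] = {}       # root -> argmin cell
    merged_at: dict[int, float] = {}     # minimum cell -> saddle level
    merged_into: dict[int, int] = {}

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    if fes.ndim == 1:
        neighbor_offsets = [(-1,), (1,)]
    else:
        neighbor_offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                            if (di, dj) != (0, 0)]

    for cell in order:
        level = flat[cell]
        if not np.isfinite(level):
            break
        idx = np.unravel_index(cell, shape)
        roots = set()
        for off in neighbor_offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(i < 0 or i >= s for i, s in zip(nb, shape)):
                continue
            ni = np.ravel_multi_index(nb, shape)
            if parent[ni] != -1:
                roots.add(find(ni))
        if not roots:
            parent[cell] = cell
            basin_min[cell] = cell
        else:
            roots = sorted(roots, key=lambda r: flat[basin_min[r]])
            main = roots[0]
            parent[cell] = main
            for other in roots[1:]:
                m_other = basin_min[other]
                merged_at[m_other] = level
                merged_into[m_other] = basin_min[main]
                parent[other] = main

    minima = []
    for cell, saddle in merged_at.items():
        value = flat[cell]
        minima.append((cell, value, saddle - value))
    # surviving minima (normally just the global one): their depth is the
    # highest saddle at which a competitor merged into them, falling back
    # to the sampled range for a single-basin landscape
    surviving = {basin_min[find(c)] for c in basin_min}
    for cell in surviving:
        value = flat[cell]
        into_me = [s for c, s in merged_at.items()
                   if merged_into.get(c) == cell]
        if into_me:
            depth = max(into_me) - value
        else:
            depth = float(np.max(flat[np.isfinite(flat)]) - value)
        minima.append((cell, value, depth))

    centers = [c for _, c in fes.axes]
    report = []
    for cell, value, depth in minima:
        if depth < min_depth or value > max_value:
            continue
        idx = np.unravel_index(cell, shape)
        loc = tuple(float(centers[d][idx[d]]) for d in range(fes.ndim))
        report.append(Minimum(location=loc, value=float(value), depth=float(depth)))
    report.sort(key=lambda m: m.value)
    return MinimaReport(report)


def convergence_series(hills: HillsLog, bias_factor: float,
                       basin_a: tuple[float, float], basin_b: tuple[float, float],
                       checkpoints: np.ndarray,
                       grid: np.ndarray | None = None) -> pd.DataFrame:
    """ΔF(t) = F(basin_a) − F(basin_b) from the bias truncated at each
    checkpoint; convergence is declared when the last three checkpoints
    vary by < 1 kJ/mol."""
    from .metad import bias_to_fes

    checkpoints = np.asarray(checkpoints, dtype=float)
    if checkpoints.size < 2:
        raise ValueError("need at least 2 checkpoints")
    if grid is None:
        span = hills.centers.max() - hills.centers.min()
        pad = 0.02 * span + 3.0 * hills.sigmas.max()
        grid = np.linspace(hills.centers.min() - pad,
                           hills.centers.max() + pad, 1024)
    rows = []
    for t in checkpoints:
        part = hills.truncated(t)
        if len(part) == 0:
            rows.append((t, np.nan))
            continue
        prof = bias_to_fes(part, bias_factor, grid)
        f = prof.values
        in_a = (grid >= basin_a[0]) & (grid <= basin_a[1])
        in_b = (grid >= basin_b[0]) & (grid <= basin_b[1])
        if not in_a.any():
            raise ValueError("basin_a contains no grid points (never sampled)")
        if not in_b.any():
            raise ValueError("basin_b contains no grid points (never sampled)")
        rows.append((t, float(f[in_a].min() - f[in_b].min())))
    df = pd.DataFrame(rows, columns=["time", "delta_f"])
    tail = df["delta_f"].iloc[-3:]
    df.attrs["converged"] = bool(tail.notna().all()
                                 and tail.max() - tail.min() < 1.0)
    return df
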