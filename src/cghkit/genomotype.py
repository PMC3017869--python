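"""Dynamic-cutoff presence/absence classification of probe log-ratios.

The observed distribution of summarized log2(query/reference) ratios is
a mixture of a dominant "present" component (symmetric around its mode,
near 0 after normalization) and a left-shifted "absent/divergent"
component. Following the mode-mirroring idea behind GACK, the present
component is estimated by reflecting the right half of the observed
density about its mode; each probe's estimated probability of presence
(EPP) is the ratio of that mirrored density to the observed density at
its ratio, clipped to [0, 1]. Probes with EPP below a threshold
(default 0.5) are called absent (0), others present (1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

GRID_SIZE = 512
DEFAULT_THRESHOLD = 0.5
MIN_VALUES = 50


@dataclass
class DensityModel:
    """Kernel density of observed M with its mirrored present component."""

    grid: np.ndarray        # regular grid over the data range
    f_obs: np.ndarray       # observed density on the grid
    f_pres: np.ndarray      # mode-mirrored present-component density
    mode: float             # m-hat; ties broken toward smaller M

    def density_at(self, x: np.ndarray, which: str = "obs") -> np.ndarray:
        f = self.f_obs if which == "obs" else self.f_pres
        return np.interp(x, self.grid, f, left=0.0, right=0.0)


def fit_density(values: np.ndarray, bandwidth: str | float = "silverman",
                grid_size: int = GRID_SIZE) -> DensityModel:
    """Gaussian KDE of the ratio distribution plus its mirrored half.

    The grid spans the data range padded by three bandwidths. The mode
    is the grid argmax (ties toward smaller M). For x < mode the present
    density is the observed density reflected about the mode,
    f_pres(x) = f_obs(2*mode - x); at and right of the mode the two
    coincide.
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_VALUES:
        raise ValueError(f"need >= {MIN_VALUES} values to fit the ratio density, "
                         f"got {values.size}")
    kde = gaussian_kde(values, bw_method=bandwidth)
    h = np.sqrt(kde.covariance[0, 0])
    lo, hi = values.min() - 3 * h, values.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    f_obs = kde(grid)
    # mode located on an oversmoothed pilot density: the argmax of the
    # raw KDE wobbles by O(h) from sampling noise, and the mirror point
    # must sit at the center of the dominant (present) component
    pilot = gaussian_kde(values, bw_method=2.0 * kde.factor)
    mode = float(grid[int(np.argmax(pilot(grid)))])  # first-index tie-break = smaller M
    f_pres = np.where(grid >= mode, f_obs,
                      np.interp(2 * mode - grid, grid, f_obs, left=0.0, right=0.0))
    return DensityModel(grid=grid, f_obs=f_obs, f_pres=f_pres, mode=mode)


def estimate_epp(model: DensityModel, values: np.ndarray) -> np.ndarray:
    """Estimated probability of presence for each ratio.

    EPP(x) = min(1, f_pres(x) / f_obs(x)); exactly 1 at and right of the
    mode. Where the observed density vanishes (far extrapolation) EPP is
    1 right of the mode and 0 left of it.
    """
    x = np.asarray(values, dtype=float)
    f_obs = model.density_at(x, "obs")
    f_pres = model.density_at(x, "pres")
    with np.errstate(divide="ignore", invalid="ignore"):
        epp = np.where(f_obs > 0, np.minimum(1.0, f_pres / f_obs), 0.0)
    epp = np.where(x >= model.mode, 1.0, epp)
    return epp


def binary_call(track: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                bandwidth: str | float = "silverman") -> pd.DataFrame:
    """Attach EPP and a 0/1 absence/presence call to a summarized track.

    ``track`` needs an M column; the density is fitted on the track's
    own ratios (classification is per strain comparison, not per array).
    call = 1 iff EPP >= threshold.
    """
    model = fit_density(track["M"].to_numpy(), bandwidth=bandwidth)
    out = track.copy()
    out["EPP"] = estimate_epp(model, track["M"].to_numpy())
    out["call"] = (out["EPP"] >= threshold).astype(int)
    return out


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pcl(path) -> pd.DataFrame:
    """Read a minimal pcl-format matrix (probe rows, one ratio column).

    pcl files carry two header columns (ID, NAME), a GWEIGHT column and
    an EWEIGHT row; only the first data column is used, as a
    single-comparison track.
    """
    raw = pd.read_csv(path, sep="\t")
    raw = raw[raw.iloc[:, 0] != "EWEIGHT"]
    data_cols = [c for c in raw.columns[2:] if c != "GWEIGHT"]
    if not data_cols:
        raise ValueError(f"{path}: no data columns in pcl file")
    return pd.DataFrame({"probe_id": raw.iloc[:, 0].astype(str),
                         "M": pd.to_numeric(raw[data_cols[0]])})
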