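"""The SCAR-seq strand-partition statistic and restoration kinetics.

Partition is (F - R)/(F + R) per genomic window, where F and R are forward-
and reverse-strand read counts from a strand-resolved nascent-chromatin
library. Around a replication initiation zone the leading daughter strand
maps to the forward strand right of the zone center and to the reverse
strand left of it, so a parental-histone mark that is preferentially
recycled to the leading strand produces an antisymmetric partition profile.
Averaging sign-oriented partition over windows with confident fork
directionality collapses a profile into a single asymmetry amplitude, whose
decay over chase time reflects how fast new histones acquire the mark:
with restored fraction rho(t) = 1 - exp(-k t), the expected amplitude is

    A(t) = b * (1 - rho(t)) / (1 + rho(t)),

b being the recycling bias of the cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .genomics_io import Track, WindowGrid

__all__ = [
    "StrandedCounts",
    "PartitionTrack",
    "OrientedProfile",
    "KineticsFit",
    "compute_partition",
    "orient_partition",
    "average_profiles",
    "asymmetry_amplitude",
    "fit_restoration_kinetics",
]


@dataclass
class StrandedCounts:
    """Per-window forward/reverse read counts for one sample x mark x time."""

    grid: WindowGrid
    forward: np.ndarray
    reverse: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward)
        self.reverse = np.asarray(self.reverse)
        if self.forward.shape != (self.grid.n,) or self.reverse.shape != (self.grid.n,):
            raise ValueError("stranded counts not aligned to grid")
        if (self.forward < 0).any() or (self.reverse < 0).any():
            raise ValueError("read counts must be non-negative")

    def flipped(self) -> "StrandedCounts":
        """Swap strand labels (F <-> R); used by equivariance checks."""
        return StrandedCounts(self.grid, self.reverse.copy(), self.forward.copy(), dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        w = self.grid.windows
        return pd.DataFrame(
            {
                "chrom": w["chrom"],
                "start": w["start"],
                "end": w["end"],
                "F": self.forward,
                "R": self.reverse,
            }
        )


@dataclass
class PartitionTrack:
    grid: WindowGrid
    values: np.ndarray  # in [-1, 1], NaN where coverage < min_coverage
    coverage: np.ndarray  # F + R
    min_coverage: int

    def as_track(self) -> Track:
        return Track(grid=self.grid, values=self.values)


def compute_partition(counts: StrandedCounts, min_coverage: int = 10) -> PartitionTrack:
    """Partition (F - R)/(F + R) per window; missing (NaN) below the coverage floor.

    A window with zero reads is missing, not zero: no data is not symmetry.
    The default floor of 10 reads bounds the variance of the ratio and is a
    flag, not a constant of nature.
    """
    F = counts.forward.astype(float)
    R = counts.reverse.astype(float)
    total = F + R
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total >= max(min_coverage, 1), (F - R) / total, np.nan)
    return PartitionTrack(grid=counts.grid, values=values, coverage=total, min_coverage=min_coverage)


@dataclass
class OrientedProfile:
    """Mean partition versus signed distance from initiation-zone centers.

    ``window_table`` retains one row per contributing (zone, window) pair so
    the asymmetry amplitude can be bootstrapped over zones.
    """

    distances: np.ndarray  # signed bin centers, bp
    mean: np.ndarray
    n: np.ndarray
    bin_size: int
    window_table: pd.DataFrame = field(repr=False)
    replicate: str = "single"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.distances, "mean_partition": self.mean, "n": self.n})


def _zone_centers(zones: pd.DataFrame) -> pd.DataFrame:
    z = zones.reset_index(drop=True)
    return pd.DataFrame(
        {"chrom": z["chrom"], "center": (z["start"] + z["end"]) // 2, "zone": z.index}
    )


def orient_partition(
    track: PartitionTrack,
    zones: pd.DataFrame,
    rfd: Track,
    flank: int = 50_000,
    rfd_threshold: float = 0.5,
    bin_size: int | None = None,
) -> OrientedProfile:
    """Collect partition values at signed distances from zone centers.

    Windows with |RFD| below ``rfd_threshold`` are excluded (ambiguous fork
    direction). The profile reports raw mean partition per signed-distance
    bin, the shape plotted in strand-asymmetry figures; per-window fork
    orientation (sign of RFD) is carried along for the scalar amplitude.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if len(zones) == 0:
        raise ValueError("no initiation zones supplied")
    bin_size = track.grid.size if bin_size is None else bin_size
    grid = track.grid
    centers_by_chrom = _zone_centers(zones)
    win_centers = grid.centers()
    rows = []
    for chrom, sub in centers_by_chrom.groupby("chrom", sort=False):
        lo, hi = grid.index_range(chrom)
        if hi <= lo:
            continue
        wc = win_centers[lo:hi]
        for zone_id, center in zip(sub["zone"], sub["center"]):
            i0 = int(np.searchsorted(wc, center - flank, side="left"))
            i1 = int(np.searchsorted(wc, center + flank, side="right"))
            if i1 <= i0:
                continue
            idx = np.arange(lo + i0, lo + i1)
            dist = wc[i0:i1] - center
            part = track.values[idx]
            r = rfd.values[idx]
            keep = np.isfinite(part) & np.isfinite(r) & (np.abs(r) >= rfd_threshold)
            if not keep.any():
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "zone": zone_id,
                        "distance": dist[keep],
                        "partition": part[keep],
                        "rfd_sign": np.sign(r[keep]),
                    }
                )
            )
    if not rows:
        raise ValueError("no window passed the RFD/coverage filters; empty profile")
    table = pd.concat(rows, ignore_index=True)
    table["bin"] = np.round(table["distance"] / bin_size).astype(int)
    grouped = table.groupby("bin")["partition"].agg(["mean", "size"])
    bins = grouped.index.to_numpy()
    return OrientedProfile(
        distances=bins * float(bin_size),
        mean=grouped["mean"].to_numpy(),
        n=grouped["size"].to_numpy(),
        bin_size=bin_size,
        window_table=table,
    )


def average_profiles(profiles: list[OrientedProfile]) -> OrientedProfile:
    """Average replicate profiles (computed per replicate first, then averaged)."""
    if not profiles:
        raise ValueError("no profiles to average")
    frames = [p.to_frame().set_index("distance") for p in profiles]
    joined = pd.concat([f["mean_partition"] for f in frames], axis=1)
    ns = pd.concat([f["n"] for f in frames], axis=1).fillna(0)
    mean = joined.mean(axis=1, skipna=True)
    table = pd.concat([p.window_table for p in profiles], ignore_index=True)
    return OrientedProfile(
        distances=mean.index.to_numpy(dtype=float),
        mean=mean.to_numpy(),
        n=ns.sum(axis=1).to_numpy(),
        bin_size=profiles[0].bin_size,
        window_table=table,
        replicate="averaged",
    )


def asymmetry_amplitude(
    profile: OrientedProfile,
    inner_exclusion: int = 1_000,
    n_boot: int = 500,
    rng: np.random.Generator | int | None = 0,
) -> dict:
    """One-number summary of an oriented profile, with a bootstrap CI over zones.

    Each window's partition is oriented by the sign of its fork direction
    (identical to the sign of its distance from the zone center for every
    window that passes the RFD filter); the amplitude is the mean oriented
    partition over windows farther than ``inner_exclusion`` from the center.
    The CI resamples zones, the independent units of the profile.
    """
    t = profile.window_table
    t = t[np.abs(t["distance"]) > inner_exclusion]
    if len(t) == 0:
        raise ValueError("all windows fall inside the inner exclusion zone")
    oriented = t["rfd_sign"].to_numpy() * t["partition"].to_numpy()
    amplitude = float(oriented.mean())
    per_zone = (
        pd.DataFrame({"zone": t["zone"].to_numpy(), "o": oriented})
        .groupby("zone")["o"]
        .agg(["mean", "size"])
    )
    zone_means = per_zone["mean"].to_numpy()
    zone_sizes = per_zone["size"].to_numpy().astype(float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nz = len(zone_means)
    if nz > 1 and n_boot > 0:
        picks = rng.integers(0, nz, size=(n_boot, nz))
        boot = (zone_means[picks] * zone_sizes[picks]).sum(axis=1) / zone_sizes[picks].sum(axis=1)
        lo, hi = np.quantile(boot, [0.025, 0.975])
        se = float(boot.std(ddof=1))
    else:
        lo = hi = amplitude
        se = float("nan")
    return {
        "amplitude": amplitude,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "se": se,
        "n_windows": int(len(t)),
        "n_zones": int(nz),
    }


# ---------------------------------------------------------------------------
# restoration kinetics
# ---------------------------------------------------------------------------


def _decay(t: np.ndarray, A0: float, k: float) -> np.ndarray:
    # A0 * (1 - rho)/(1 + rho) with rho = 1 - exp(-k t)
    e = np.exp(-k * t)
    return A0 * e / (2.0 - e)


def _wave(t: np.ndarray, w: float, tau: float) -> np.ndarray:
    return w * (1.0 + t / tau) * np.exp(-t / tau)


@dataclass
class KineticsFit:
    model: str
    params: dict
    times: np.ndarray
    observed: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    lack_of_fit: bool

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = _decay(t, self.params["A0"], self.params["k"])
        if self.model == "wave_plus_decay":
            out = out + _wave(t, self.params["wave"], self.params["tau"])
        return out


def fit_restoration_kinetics(
    times,
    amplitudes,
    model: str = "exp_decay",
    lack_of_fit_tol: float = 0.15,
) -> KineticsFit:
    """Fit amplitude-versus-chase-time to the dilution model.

    ``exp_decay`` fits A(t) = A0 exp(-kt)/(2 - exp(-kt)), the amplitude of a
    parental mark whose new-histone restoration follows rho(t) = 1 - exp(-kt).
    ``wave_plus_decay`` adds a transient w (1 + t/tau) exp(-t/tau) term for
    marks carried on new histones (non-monotone amplitude). Fits are least
    squares; non-monotone data under exp_decay still fit but are flagged
    through a relative-residual lack-of-fit test.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValueError("times and amplitudes must be equal-length 1-D arrays")
    min_pts = 3 if model == "exp_decay" else 4
    if len(t) < min_pts:
        raise ValueError(f"{model} needs at least {min_pts} time points")

    if model == "exp_decay":
        def resid(p):
            return _decay(t, p[0], p[1]) - a

        k0 = 0.5
        if len(t) >= 2 and abs(a[0]) > 1e-12 and abs(a[-1]) > 1e-12 and t[-1] > t[0]:
            ratio = abs(a[-1] / a[0])
            if 0 < ratio < 1:
                k0 = max(-np.log(ratio) / (t[-1] - t[0]), 1e-3)
        best = None
        for k_init in (k0, 0.05, 0.3, 1.0, 3.0):
            sol = optimize.least_squares(
                resid, x0=[a[0] if a[0] != 0 else 0.1, k_init],
                bounds=([-1.5, 0.0], [1.5, 50.0]), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        params = {"A0": float(best.x[0]), "k": float(best.x[1])}
    elif model == "wave_plus_decay":
        def resid(p):
            return _decay(t, p[0], p[1]) + _wave(t, p[2], p[3]) - a

        best = None
        for w_init in (a[0], -abs(a).max(), abs(a).max()):
            for tau_init in (0.5, 1.0, 2.0):
                sol = optimize.least_squares(
                    resid, x0=[a[-1], 0.3, w_init, tau_init],
                    bounds=([-1.5, 0.0, -2.0, 0.1], [1.5, 50.0, 2.0, 8.0]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        params = {
            "A0": float(best.x[0]),
            "k": float(best.x[1]),
            "wave": float(best.x[2]),
            "tau": float(best.x[3]),
        }
    else:
        raise ValueError(f"unknown kinetics model {model!r}")

    fit = KineticsFit(
        model=model,
        params=params,
        times=t,
        observed=a,
        fitted=np.empty(0),
        residuals=np.empty(0),
        lack_of_fit=False,
    )
    fit.fitted = fit.predict(t)
    fit.residuals = a - fit.fitted
    scale = max(np.abs(a).max(), 1e-12)
    fit.lack_of_fit = bool(np.sqrt(np.mean(fit.residuals**2)) / scale > lack_of_fit_tol)
    return fit
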