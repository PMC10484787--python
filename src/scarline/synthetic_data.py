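"""Forward simulator of replication-coupled histone recycling and restoration.

Every input the pipeline consumes can be generated here with known ground
truth: a replication landscape (initiation zones, termination midpoints,
fork-directionality track), strand-resolved nascent-chromatin read counts
under a tunable parental-recycling bias, spike-in-scaled binned ChIP counts
with planted global and local occupancy changes, repeat subfamilies with
controlled multimapping structure, and promoter mark signals with planted
chromatin-state classes.

The recycling model: during replication each window's complement of parental
nucleosomes is split between the two daughter strands, the leading strand
receiving each parental nucleosome with probability (1 + b)/2 (b = +1 routes
everything to the leading strand, b = -1 to the lagging strand, b = 0 is the
symmetric wild type). Slots not filled by parental histones receive new
histones, which carry a given mark with probability pi_n(t) that rises with
chase time t as restoration proceeds (and may include a transient
acetylation-like wave). Parental nucleosomes are rerouted, never lost: in
every replication event leading + lagging parental counts equal the parental
input count exactly.

Expected oriented partition in a fully parental-marked domain:
b (pi_p - pi_n) / (pi_p + pi_n), which for pi_n = pi_p * rho(t) reduces to
the closed form b (1 - rho)/(1 + rho).
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics_io import (
    GenomeLayout,
    Track,
    WindowGrid,
    make_windows,
    overlap_windows,
    write_bed,
    write_bedgraph,
)
from .scar_partition import StrandedCounts

__all__ = [
    "child_rng",
    "ReplicationLandscape",
    "simulate_landscape",
    "MarkKinetics",
    "RecyclingModel",
    "DEFAULT_MARKS",
    "SCENARIO_BIAS",
    "replicate_nucleosomes",
    "simulate_scarseq_counts",
    "simulate_qchip_counts",
    "QChipSimulation",
    "simulate_repeat_counts",
    "RepeatSimulation",
    "simulate_repeat_reads",
    "simulate_promoter_signals",
    "simulate_change_matrix",
    "simulate_experiment",
]


def child_rng(seed: int, *labels) -> np.random.Generator:
    """Derive an independent child stream from (seed, operation, label...).

    A single top-level seed plus stable string hashing gives reproducibility
    with stream independence across operations and samples.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        entropy.append(zlib.crc32(str(lab).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# replication landscape
# ---------------------------------------------------------------------------


@dataclass
class ReplicationLandscape:
    """Initiation zones, termination midpoints, fork direction, and RFD.

    ``fork_direction`` is the deterministic all-zones-fire geometry: +1
    immediately right of a zone center, -1 immediately left, flipping at the
    termination midpoint between adjacent zones (0 exactly at boundaries).
    ``rfd`` is the firing-efficiency-weighted expectation of fork direction:
    the probability that the nearest *fired* zone lies left of the position,
    minus the probability it lies right (equidistant fired zones terminate).
    """

    layout: GenomeLayout
    zones: pd.DataFrame  # chrom, start, end, efficiency

    def zone_centers(self, chrom: str) -> np.ndarray:
        sub = self.zones[self.zones["chrom"] == chrom]
        return ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)

    def termination_midpoints(self, chrom: str) -> np.ndarray:
        c = np.sort(self.zone_centers(chrom))
        return (c[:-1] + c[1:]) / 2.0

    def fork_direction(self, chrom: str, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        centers = np.sort(self.zone_centers(chrom)).astype(float)
        if centers.size == 0:
            return np.zeros_like(pos)
        mids = (centers[:-1] + centers[1:]) / 2.0
        # nearest-center rule == sign alternating across (c1, m1, c2, m2, ...)
        nearest = np.argmin(np.abs(pos[:, None] - centers[None, :]), axis=1)
        sign = np.sign(pos - centers[nearest])
        sign[np.isin(pos, mids)] = 0.0
        return sign

    def rfd(self, chrom: str, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        sub = self.zones[self.zones["chrom"] == chrom]
        centers = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(float)
        eff = sub["efficiency"].to_numpy(dtype=float)
        order = np.argsort(centers)
        centers, eff = centers[order], eff[order]
        if centers.size == 0:
            return np.zeros_like(pos)
        out = np.empty(pos.shape, dtype=float)
        for i, x in enumerate(pos):
            d = np.abs(x - centers)
            o = np.argsort(d, kind="stable")
            ds, es, cs = d[o], eff[o], centers[o]
            surv_before = np.concatenate([[1.0], np.cumprod(1.0 - es)[:-1]])
            # group ties: determiner must be the unique fired zone at the
            # minimal distance (an equidistant fired partner means termination)
            p = np.zeros(len(ds))
            j = 0
            prefix = 1.0
            while j < len(ds):
                jend = j
                while jend + 1 < len(ds) and ds[jend + 1] == ds[j]:
                    jend += 1
                group = slice(j, jend + 1)
                gsurv = np.prod(1.0 - es[group])
                for g in range(j, jend + 1):
                    others = np.prod(1.0 - np.delete(es[group], g - j))
                    p[g] = es[g] * prefix * others
                prefix *= gsurv
                j = jend + 1
            signs = np.sign(x - cs)
            out[i] = float(np.sum(p * signs))
        return out

    def rfd_track(self, grid: WindowGrid) -> Track:
        values = np.empty(grid.n)
        centers = grid.centers()
        for chrom in grid.layout.names:
            lo, hi = grid.index_range(chrom)
            if hi > lo:
                values[lo:hi] = self.rfd(chrom, centers[lo:hi])
        return Track(grid=grid, values=values)


def simulate_landscape(
    layout: GenomeLayout,
    n_zones: int,
    spacing: str = "even",
    zone_width: int = 5_000,
    efficiency: float | tuple[float, float] = 1.0,
    jitter: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> ReplicationLandscape:
    """Place ``n_zones`` initiation zones per chromosome.

    ``spacing='even'`` spreads centers evenly with fractional jitter;
    ``spacing='uniform'`` draws them uniformly at random (sorted, deduplicated
    spacing enforced at one zone width). Efficiency is a constant or a
    (low, high) range sampled per zone.
    """
    if n_zones < 1:
        raise ValueError("need at least one zone per chromosome")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "landscape")
    rows = []
    for chrom, length in layout.chroms:
        spacing_bp = length / n_zones
        if zone_width >= spacing_bp:
            raise ValueError("zones denser than their width; shrink zone_width or n_zones")
        if spacing == "even":
            centers = (np.arange(n_zones) + 0.5) * spacing_bp
            centers = centers + rng.uniform(-jitter, jitter, n_zones) * spacing_bp
        elif spacing == "uniform":
            centers = np.sort(rng.uniform(zone_width, length - zone_width, n_zones))
            centers = np.maximum.accumulate(centers + np.arange(n_zones) * 1e-9)
        else:
            raise ValueError(f"unknown spacing model {spacing!r}")
        centers = np.clip(centers, zone_width / 2, length - zone_width / 2).astype(np.int64)
        if np.isscalar(efficiency):
            eff = np.full(n_zones, float(efficiency))
        else:
            eff = rng.uniform(efficiency[0], efficiency[1], n_zones)
        for c, e in zip(centers, eff):
            rows.append((chrom, int(c - zone_width // 2), int(c + zone_width // 2), float(e)))
    zones = pd.DataFrame(rows, columns=["chrom", "start", "end", "efficiency"])
    if ((zones["efficiency"] <= 0) | (zones["efficiency"] > 1)).any():
        raise ValueError("firing efficiency must lie in (0, 1]")
    return ReplicationLandscape(layout=layout, zones=zones)


# ---------------------------------------------------------------------------
# recycling model and SCAR-seq counts
# ---------------------------------------------------------------------------


@dataclass
class MarkKinetics:
    """Per-mark restoration parameters.

    parental_prob   probability a parental histone inside the mark's domain
                    carries the mark (pi_p)
    restoration_rate k (per hour): new histones approach pi_p with
                    rho(t) = 1 - exp(-k t)
    wave_amplitude  a0 of the transient new-histone wave a(t) =
                    a0 (1 + c t) exp(-t/tau); zero for parental-type marks
    """

    parental_prob: float = 1.0
    restoration_rate: float = 0.1
    wave_amplitude: float = 0.0
    wave_tau: float = 2.0
    wave_linear: float = 1.0

    def new_prob(self, t: float) -> float:
        if self.restoration_rate < 0:
            raise ValueError("restoration rate must be non-negative")
        rho = 1.0 - np.exp(-self.restoration_rate * t)
        wave = self.wave_amplitude * (1.0 + self.wave_linear * t) * np.exp(-t / self.wave_tau)
        return float(np.clip(self.parental_prob * rho + wave, 0.0, 1.0))


#: Restoration kinetics emulating the qualitative per-mark behavior: slow
#: repressive marks with residual asymmetry at 8 h, fast H3K4me3 restored
#: before 3 h, and an H3K27ac-like new-histone wave peaking near 1 h.
DEFAULT_MARKS: dict[str, MarkKinetics] = {
    "H3K27me3": MarkKinetics(parental_prob=1.0, restoration_rate=0.08),
    "H3K9me3": MarkKinetics(parental_prob=1.0, restoration_rate=0.06),
    "H3K4me3": MarkKinetics(parental_prob=1.0, restoration_rate=1.0),
    "H3K27ac": MarkKinetics(
        parental_prob=0.2, restoration_rate=0.6, wave_amplitude=0.5, wave_tau=2.0
    ),
}

#: Scenario recycling biases. Magnitudes are synthetic free parameters, not
#: estimates from any dataset: the mutant routes parental histones to the
#: leading strand, the POLE4 knockout to the lagging strand with smaller
#: magnitude, and the revertant restores symmetry.
SCENARIO_BIAS: dict[str, float] = {
    "WT": 0.0,
    "MCM2-2A": 0.7,
    "POLE4-KO": -0.3,
    "MCM2-R": 0.0,
}


@dataclass
class RecyclingModel:
    bias: float = 0.0
    marks: dict[str, MarkKinetics] = field(default_factory=lambda: dict(DEFAULT_MARKS))
    depth: float = 100.0  # mean reads/window at full marking of both strands
    noise: str = "nb"  # "nb" or "poisson"
    dispersion: float = 0.05
    nucleosome_spacing: int = 200
    background: float = 0.02  # mark probability outside domains

    def __post_init__(self) -> None:
        if abs(self.bias) > 1:
            raise ValueError("recycling bias must lie in [-1, 1]")
        if self.noise not in ("nb", "poisson"):
            raise ValueError("noise must be 'nb' or 'poisson'")


def replicate_nucleosomes(
    n_parental: np.ndarray | int, bias: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split parental nucleosomes between daughters; conservation is exact.

    Leading-strand count is Binomial(n, (1+b)/2); the lagging strand receives
    the remainder, so leading + lagging == n in every event (rerouting, not
    loss).
    """
    if abs(bias) > 1:
        raise ValueError("recycling bias must lie in [-1, 1]")
    n = np.asarray(n_parental, dtype=np.int64)
    leading = rng.binomial(n, (1.0 + bias) / 2.0)
    lagging = n - leading
    return leading, lagging


def _draw_counts(mu: np.ndarray, model: RecyclingModel, rng: np.random.Generator) -> np.ndarray:
    mu = np.clip(mu, 1e-12, None)
    if model.noise == "poisson" or model.dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / model.dispersion
    # NB as Gamma-Poisson mixture keeps the mean exact for non-integer r
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_scarseq_counts(
    landscape: ReplicationLandscape,
    model: RecyclingModel,
    mark: str,
    t: float,
    grid: WindowGrid,
    domains: pd.DataFrame | None = None,
    rfd: Track | None = None,
    seed: int | np.random.Generator = 0,
) -> StrandedCounts:
    """Strand-resolved read counts for one mark at chase time ``t`` hours.

    Per window one replication event is simulated at nucleosome granularity:
    parental nucleosomes split binomially between daughters (exact
    conservation), marked mass on each daughter follows the mark's parental
    and new-histone probabilities, and reads are drawn around the marked
    densities. Convention: forward reads correspond to the leading daughter
    strand wherever fork direction is +1; windows with intermediate RFD mix
    the two orientations with probability (1 + RFD)/2.
    """
    if t < 0:
        raise ValueError("chase time must be non-negative")
    kin = model.marks[mark]
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "scarseq", mark, t)
    if rfd is None:
        rfd = landscape.rfd_track(grid)
    p_right = (1.0 + rfd.values) / 2.0

    in_domain = (
        overlap_windows(grid, domains) if domains is not None else np.ones(grid.n, dtype=bool)
    )
    pi_p = np.where(in_domain, kin.parental_prob, model.background)
    pi_n = np.where(in_domain, kin.new_prob(t), model.background)

    sizes = (grid.windows["end"] - grid.windows["start"]).to_numpy()
    n_nuc = np.maximum(sizes // model.nucleosome_spacing, 1).astype(np.int64)
    lead_par, lag_par = replicate_nucleosomes(n_nuc, model.bias, rng)
    assert np.array_equal(lead_par + lag_par, n_nuc)  # parental mass conserved

    m_lead = lead_par * pi_p + (n_nuc - lead_par) * pi_n
    m_lag = lag_par * pi_p + (n_nuc - lag_par) * pi_n
    mu_f = model.depth * (p_right * m_lead + (1 - p_right) * m_lag) / (2.0 * n_nuc)
    mu_r = model.depth * (p_right * m_lag + (1 - p_right) * m_lead) / (2.0 * n_nuc)

    F = _draw_counts(mu_f, model, rng)
    R = _draw_counts(mu_r, model, rng)
    meta = {"mark": mark, "t": float(t), "bias": model.bias, "noise": model.noise}
    return StrandedCounts(grid=grid, forward=F, reverse=R, meta=meta)


# ---------------------------------------------------------------------------
# spike-in quantitative ChIP counts
# ---------------------------------------------------------------------------


@dataclass
class QChipSimulation:
    counts: pd.DataFrame  # bins x samples
    spike_totals: pd.Series
    sample_info: pd.DataFrame  # sample, condition, replicate, depth
    truth: dict


def simulate_qchip_counts(
    n_bins: int = 2_000,
    replicates: int = 3,
    global_scale: dict[str, float] | None = None,
    local_changes: dict[str, tuple[float, float]] | None = None,
    baseline_mean: float = 250.0,
    depth_jitter: float = 0.15,
    depth_override: dict[str, float] | None = None,
    spike_fraction: float = 0.025,
    dispersion: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> QChipSimulation:
    """Binned ChIP counts with companion spike-in totals and planted truth.

    Genome bin counts are NB with mean proportional to occupancy x sample
    depth; spike-in totals are proportional to depth only (the spike genome's
    occupancy is fixed across samples), so a planted global occupancy change
    is recoverable solely through the spike-in. ``local_changes`` plants
    per-bin fold changes in a recorded random subset:
    condition -> (fraction_of_bins, fold).
    """
    if not (0 < spike_fraction <= 0.2):
        raise ValueError("spike fraction must lie in (0, 0.2]")
    if replicates < 2:
        warnings.warn("fewer than 2 replicates: the differential test will refuse")
    global_scale = {"WT": 1.0, "MUT": 1.0} if global_scale is None else dict(global_scale)
    local_changes = {} if local_changes is None else dict(local_changes)
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "qchip")

    baseline = rng.gamma(shape=3.0, scale=baseline_mean / 3.0, size=n_bins)
    truth: dict = {"global_scale": dict(global_scale), "local": {}}
    occupancy = {}
    for cond, scale in global_scale.items():
        occ = baseline * scale
        if cond in local_changes:
            frac, fold = local_changes[cond]
            n_changed = int(round(frac * n_bins))
            changed = rng.choice(n_bins, size=n_changed, replace=False)
            occ = occ.copy()
            occ[changed] *= fold
            truth["local"][cond] = {"bins": np.sort(changed).tolist(), "fold": float(fold)}
        occupancy[cond] = occ

    samples, conds, reps, depths, cols = [], [], [], [], {}
    spike_base = spike_fraction * n_bins * baseline_mean
    r = 1.0 / dispersion if dispersion > 0 else None
    spike_totals = {}
    for cond in global_scale:
        for rep in range(1, replicates + 1):
            name = f"{cond}_rep{rep}"
            depth = float(np.exp(rng.normal(0.0, depth_jitter)))
            if depth_override and name in depth_override:
                depth = float(depth_override[name])
            mu = occupancy[cond] * depth
            if r is None:
                y = rng.poisson(mu)
            else:
                y = rng.poisson(rng.gamma(shape=r, scale=mu / r))
            cols[name] = y
            spike_totals[name] = int(rng.poisson(spike_base * depth))
            samples.append(name)
            conds.append(cond)
            reps.append(rep)
            depths.append(depth)
    counts = pd.DataFrame(cols, index=pd.RangeIndex(n_bins, name="bin"))
    info = pd.DataFrame(
        {"sample": samples, "condition": conds, "replicate": reps, "depth": depths}
    )
    return QChipSimulation(
        counts=counts,
        spike_totals=pd.Series(spike_totals, name="spike_total"),
        sample_info=info,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# repeat subfamilies
# ---------------------------------------------------------------------------

_REPEAT_FAMILIES = ("LTR/ERVK", "LTR/ERV1", "LTR/ERVL", "LINE/L1", "SINE/B2", "DNA/hAT")


@dataclass
class RepeatSimulation:
    ptm_counts: pd.DataFrame  # subfamily x samples (total read mass)
    unique_counts: pd.DataFrame
    multi_counts: pd.DataFrame
    rna_counts: pd.DataFrame
    library_sizes: pd.Series
    sample_info: pd.DataFrame
    rna_sample_info: pd.DataFrame
    subfamilies: pd.DataFrame  # subfamily, family, multimapping_rate
    truth: dict


def simulate_repeat_counts(
    n_subfamilies: int = 200,
    replicates: int = 3,
    rna_replicates: int = 4,
    conditions: tuple[str, str] = ("WT", "MUT"),
    planted_frac: float = 0.1,
    planted_log2fc: float = -1.0,
    multimapping_rate: tuple[float, float] = (0.2, 0.9),
    rna_coupling: float = 1.0,
    rna_noise_sd: float = 0.15,
    mean_reads_per_subfamily: float = 400.0,
    nonrepeat_reads: float = 2.0e5,
    dispersion: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> RepeatSimulation:
    """Per-subfamily ChIP read masses plus coupled RNA counts.

    A recorded subset of subfamilies gets a planted PTM log2 fold change in
    the second condition (default: loss). RNA log2 fold changes are
    ``-rna_coupling`` times the planted PTM change plus noise, so mark loss
    drives derepression and the change-change correlation has a known sign.
    Multimapping rates are per-subfamily (drawn from the given range) and the
    library size includes a fixed non-repeat read mass so whole-library
    multimapping fractions respond to planted repeat losses.
    """
    if not (0 <= multimapping_rate[0] <= multimapping_rate[1] <= 1):
        raise ValueError("multimapping rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "repeats")
    fams = [
        _REPEAT_FAMILIES[i % len(_REPEAT_FAMILIES)] for i in range(n_subfamilies)
    ]
    names = [f"{fams[i].split('/')[-1]}-sf{i:03d}" for i in range(n_subfamilies)]
    mm_rate = rng.uniform(multimapping_rate[0], multimapping_rate[1], n_subfamilies)
    abundance = rng.lognormal(mean=np.log(mean_reads_per_subfamily), sigma=0.6, size=n_subfamilies)

    n_changed = int(round(planted_frac * n_subfamilies))
    changed = np.sort(rng.choice(n_subfamilies, size=n_changed, replace=False))
    ptm_lfc = np.zeros(n_subfamilies)
    ptm_lfc[changed] = planted_log2fc
    rna_lfc = -rna_coupling * ptm_lfc + rng.normal(0.0, rna_noise_sd, n_subfamilies)

    r = 1.0 / dispersion if dispersion > 0 else None

    def nb(mu):
        if r is None:
            return rng.poisson(mu)
        return rng.poisson(rng.gamma(shape=r, scale=np.clip(mu, 1e-12, None) / r))

    cond_a, cond_b = conditions
    ptm_cols, uniq_cols, multi_cols, lib, samples, conds, reps = {}, {}, {}, {}, [], [], []
    for cond in conditions:
        mult = 2.0 ** ptm_lfc if cond == cond_b else np.ones(n_subfamilies)
        for rep in range(1, replicates + 1):
            name = f"{cond}_rep{rep}"
            total = nb(abundance * mult).astype(float)
            multi = rng.binomial(total.astype(np.int64), mm_rate).astype(float)
            ptm_cols[name] = total
            multi_cols[name] = multi
            uniq_cols[name] = total - multi
            lib[name] = float(total.sum() + nonrepeat_reads)
            samples.append(name)
            conds.append(cond)
            reps.append(rep)
    rna_cols = {}
    rna_abund = rng.lognormal(mean=np.log(200.0), sigma=0.6, size=n_subfamilies)
    rna_samples = []
    for cond in conditions:
        mult = 2.0 ** rna_lfc if cond == cond_b else np.ones(n_subfamilies)
        for rep in range(1, rna_replicates + 1):
            name = f"{cond}_rna{rep}"
            rna_cols[name] = nb(rna_abund * mult)
            rna_samples.append((name, cond, rep))
    idx = pd.Index(names, name="subfamily")
    return RepeatSimulation(
        ptm_counts=pd.DataFrame(ptm_cols, index=idx),
        unique_counts=pd.DataFrame(uniq_cols, index=idx),
        multi_counts=pd.DataFrame(multi_cols, index=idx),
        rna_counts=pd.DataFrame(rna_cols, index=idx),
        library_sizes=pd.Series(lib, name="library_size"),
        sample_info=pd.DataFrame(
            {"sample": samples, "condition": conds, "replicate": reps}
        ),
        rna_sample_info=pd.DataFrame(
            rna_samples, columns=["sample", "condition", "replicate"]
        ),
        subfamilies=pd.DataFrame(
            {"subfamily": names, "family": fams, "multimapping_rate": mm_rate}
        ),
        truth={
            "changed_subfamilies": [names[i] for i in changed],
            "ptm_log2fc": float(planted_log2fc),
            "rna_coupling": float(rna_coupling),
        },
    )


def simulate_repeat_reads(
    copies: pd.DataFrame,
    n_reads: int = 1_000,
    multimapping_rate: float = 0.3,
    read_length: int = 50,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Read-level alignment records over repeat copies, for aggregation tests.

    ``copies`` needs columns chrom/start/end/subfamily. A multimapping read
    aligns once to each of 2-4 random copies of one subfamily (rows share the
    read_id); a unique read aligns to a single copy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "repeat_reads")
    copies = copies.reset_index(drop=True)
    by_sf = {sf: sub.index.to_numpy() for sf, sub in copies.groupby("subfamily")}
    rows = []
    for read_id in range(n_reads):
        sf = rng.choice(list(by_sf))
        pool = by_sf[sf]
        if rng.random() < multimapping_rate and len(pool) >= 2:
            k = int(rng.integers(2, min(4, len(pool)) + 1))
            picks = rng.choice(pool, size=k, replace=False)
        else:
            picks = [rng.choice(pool)]
        for c in picks:
            start = int(copies.at[c, "start"])
            end = int(copies.at[c, "end"])
            s = int(rng.integers(start, max(end - read_length, start) + 1))
            rows.append((f"read{read_id:06d}", copies.at[c, "chrom"], s, s + read_length))
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# promoter states and change matrices
# ---------------------------------------------------------------------------

#: Planted class proportions are constructed so that each mark's "high"
#: population holds exactly one third of the features, aligning with the
#: scale-free upper-tertile threshold: H3K4me3 high in active+bivalent,
#: H3K27me3 high in bivalent+polycomb, H3K9me3 high in heterochromatic.
DEFAULT_STATE_PROBS = {
    "active": 1.0 / 3.0 - 0.13,
    "bivalent": 0.13,
    "polycomb": 1.0 / 3.0 - 0.13,
    "heterochromatic": 1.0 / 3.0,
    "quiescent": 0.13,
}

_STATE_HIGH = {
    "active": {"H3K4me3"},
    "bivalent": {"H3K4me3", "H3K27me3"},
    "polycomb": {"H3K27me3"},
    "heterochromatic": {"H3K9me3"},
    "quiescent": set(),
}


def simulate_promoter_signals(
    n: int = 2_000,
    class_probs: dict[str, float] | None = None,
    high_mean: float = 3.0,
    low_mean: float = 0.0,
    sd: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-promoter mark signals with a planted chromatin-state class.

    High/low signal components are well-separated log-scale Gaussians, and
    class counts are apportioned deterministically (largest remainder) rather
    than drawn multinomially: the recovery metric then measures the state
    assigner, not the binomial noise of the class-count draw, and each mark's
    high-signal share sits at the tertile so the scale-free cut lands in the
    gap between modes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "promoter_signals")
    probs = DEFAULT_STATE_PROBS if class_probs is None else class_probs
    states = list(probs)
    p = np.asarray([probs[s] for s in states], dtype=float)
    p = p / p.sum()
    counts = np.floor(p * n).astype(int)
    frac = p * n - counts
    for idx in np.argsort(frac)[::-1][: n - counts.sum()]:
        counts[idx] += 1
    assigned = np.repeat(np.asarray(states, dtype=object), counts)
    rng.shuffle(assigned)
    out = {"true_state": assigned}
    for mark in ("H3K4me3", "H3K27me3", "H3K9me3"):
        high = np.array([mark in _STATE_HIGH[s] for s in assigned])
        out[mark] = np.where(
            high, rng.normal(high_mean, sd, n), rng.normal(low_mean, sd, n)
        )
    return pd.DataFrame(out)


def simulate_change_matrix(
    n_features: int = 300,
    n_groups: int = 3,
    separation: float = 4.0,
    noise_sd: float = 0.5,
    columns: tuple[str, ...] = ("dH3K9me3", "dRNA", "dH3K27me3", "dH3K27ac", "dH3K4me3"),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Multi-mark change profiles with planted well-separated groups."""
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "change_matrix")
    centers = rng.normal(0.0, separation, size=(n_groups, len(columns)))
    labels = rng.integers(0, n_groups, size=n_features)
    data = centers[labels] + rng.normal(0.0, noise_sd, size=(n_features, len(columns)))
    df = pd.DataFrame(data, columns=list(columns))
    df.index = [f"feat{i:04d}" for i in range(n_features)]
    return df, labels


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


def simulate_experiment(
    outdir,
    scenario: str = "MCM2-2A",
    marks: tuple[str, ...] = ("H3K27me3", "H3K4me3", "H3K27ac"),
    times: tuple[float, ...] = (0.0, 1.0, 3.0, 8.0),
    chrom_length: int = 5_000_000,
    n_zones: int = 25,
    window: int = 1_000,
    seed: int = 0,
) -> dict:
    """Emit a full SCAR-seq pulse-chase scenario to text files with ground truth.

    Writes stranded count TSVs per mark x time, zones BED, RFD bedGraph and a
    ground-truth JSON; identical seeds give byte-identical outputs.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = GenomeLayout.from_dict({"chr1": chrom_length})
    grid = make_windows(layout, window)
    landscape = simulate_landscape(layout, n_zones=n_zones, seed=seed)
    rfd = landscape.rfd_track(grid)
    bias = SCENARIO_BIAS[scenario]
    model = RecyclingModel(bias=bias)

    zones_bed = landscape.zones.assign(name=[f"IZ{i}" for i in range(len(landscape.zones))])
    write_bed(zones_bed[["chrom", "start", "end", "name"]], outdir / "zones.bed")
    write_bedgraph(rfd, outdir / "rfd.bedGraph")

    truth = {
        "scenario": scenario,
        "bias": bias,
        "marks": {
            m: {
                "parental_prob": model.marks[m].parental_prob,
                "restoration_rate": model.marks[m].restoration_rate,
                "wave_amplitude": model.marks[m].wave_amplitude,
            }
            for m in marks
        },
        "times": list(times),
        "seed": seed,
    }
    for mark in marks:
        for t in times:
            sc = simulate_scarseq_counts(
                landscape, model, mark, t, grid, rfd=rfd, seed=child_rng(seed, scenario, mark, t)
            )
            sc.to_frame().to_csv(
                outdir / f"{scenario}_{mark}_T{t:g}.counts.tsv", sep="\t", index=False
            )
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
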