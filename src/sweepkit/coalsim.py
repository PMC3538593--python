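"""Coalescent simulation engine for null distributions.

Simulates sample genealogies under the standard neutral model (SNM) or a
piecewise-constant demography (e.g. a bottleneck), with mutations placed on
branches at rate theta = 4*N0*mu per site. Time is measured in units of 4*N0
generations (ms convention): with k lineages the total coalescence rate is
k(k-1), scaled by 1/(size_ratio * inheritance_factor) within each epoch.

Recombination is handled by an independent-windows approximation: the locus
is split into windows in proportion to its total scaled recombination rate
(input per site in 2N units, converted internally by a factor of 2 to the
4N0 scale); each window receives an independent marginal genealogy, i.e.
complete linkage within a window and free recombination between windows.
With rho = 0 the locus is a single window and the engine is the exact
standard coalescent.

Fixed-S conditioning follows the rejection-algorithm recipe: draw theta from
a uniform prior, simulate, and keep only replicates whose total segregating-
site count equals the target exactly; the acceptance rate and the accepted
theta values are recorded.

Sweep-conditioned genealogies implement an instantaneous partial sweep at a
given time: each lineage alive at the sweep escapes independently with the
model's escape probability, all non-escaping lineages coalesce into one, and
the process continues neutrally above the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml


@dataclass
class DemographyModel:
    """Piecewise-constant population-size history.

    epochs: list of (start time in 4N0 units, N(t)/N0 ratio); the first epoch
    must start at 0 and times must be strictly increasing. The inheritance
    factor (1 autosomal, 3/4 X-linked) scales the effective size.
    """

    epochs: list[tuple[float, float]]
    inheritance_factor: float = 1.0
    label: str = "custom"

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("demography needs at least one epoch")
        times = [t for t, _ in self.epochs]
        if times[0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(r <= 0 for _, r in self.epochs):
            raise ValueError("size ratios must be positive")
        if self.inheritance_factor <= 0:
            raise ValueError("inheritance factor must be positive")

    @classmethod
    def snm(cls, inheritance_factor: float = 1.0) -> "DemographyModel":
        return cls(epochs=[(0.0, 1.0)], inheritance_factor=inheritance_factor,
                   label="SNM")

    @classmethod
    def bottleneck(
        cls,
        t_start: float,
        duration: float,
        severity: float,
        ancestral_ratio: float = 1.0,
        inheritance_factor: float = 1.0,
    ) -> "DemographyModel":
        """Crash to `severity` x N0 at t_start (4N0 units) for `duration`."""
        return cls(
            epochs=[(0.0, 1.0), (t_start, severity), (t_start + duration, ancestral_ratio)],
            inheritance_factor=inheritance_factor,
            label="BN",
        )

    @classmethod
    def from_yaml(cls, path) -> "DemographyModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            epochs=[(float(t), float(r)) for t, r in cfg["epochs"]],
            inheritance_factor=float(cfg.get("inheritance_factor", 1.0)),
            label=str(cfg.get("label", "custom")),
        )

    @property
    def is_snm(self) -> bool:
        return len(self.epochs) == 1 and self.epochs[0][1] == 1.0


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    theta / theta_prior are per site (4N0 units); rho_per_site is the
    population recombination rate per nucleotide in 2N units (the usual
    genetic-map-based convention), converted internally by a factor of 2.
    """

    n: int
    L: int
    theta: Optional[float] = None
    theta_prior: Optional[tuple[float, float]] = None
    fixed_S: Optional[int] = None
    rho_per_site: float = 0.0
    finite_sites: bool = False
    reps: int = 1000
    seed: Optional[int] = None
    n_windows: Optional[int] = None
    min_acceptance: float = 1e-4

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        if self.L < 1:
            raise ValueError("locus length must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.theta_prior is not None:
            lo, hi = self.theta_prior
            if not (0 <= lo < hi):
                raise ValueError("theta prior must satisfy 0 <= low < high")
        if self.rho_per_site < 0:
            raise ValueError("recombination rate must be >= 0")

    @property
    def rho4N_per_site(self) -> float:
        return 2.0 * self.rho_per_site

    def windows(self) -> list[tuple[float, float]]:
        """(start, width) spans of the independent marginal-genealogy windows."""
        if self.n_windows is not None:
            W = max(1, min(self.L, self.n_windows))
        elif self.rho_per_site <= 0:
            W = 1
        else:
            rho_locus = self.rho4N_per_site * self.L
            W = int(np.clip(round(rho_locus), 1, min(self.L, 256)))
        edges = np.linspace(0.0, float(self.L), W + 1)
        return [(float(a), float(b - a)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class SimulationReplicateSet:
    """Null-distribution draws with their configuration and seed.

    positions[r] / counts[r]: per-replicate segregating-site positions (bp,
    possibly fractional under infinite sites) and derived-allele counts
    (count -1 flags a multiallelic finite-sites outcome, excluded from SFS).
    """

    config: SimulationConfig
    demography: DemographyModel
    positions: list[np.ndarray]
    counts: list[np.ndarray]
    thetas: np.ndarray
    tree_lengths: np.ndarray
    tmrcas: np.ndarray
    acceptance_rate: Optional[float] = None
    seed: Optional[int] = None

    @property
    def reps(self) -> int:
        return len(self.counts)

    @property
    def S(self) -> np.ndarray:
        return np.array([int(np.sum(c != 0)) for c in self.counts])

    def sfs_matrix(self) -> np.ndarray:
        """(reps, n-1) unfolded SFS counts; multiallelic outcomes excluded."""
        n = self.config.n
        out = np.zeros((self.reps, n - 1), dtype=int)
        for r, c in enumerate(self.counts):
            c = c[(c >= 1) & (c <= n - 1)].astype(int)
            out[r] = np.bincount(c, minlength=n)[1:n]
        return out

    def pi_counts(self) -> np.ndarray:
        """Mean pairwise difference count per replicate (biallelic sites)."""
        n = self.config.n
        out = np.empty(self.reps)
        denom = n * (n - 1) / 2.0
        for r, c in enumerate(self.counts):
            k = c[(c >= 1) & (c <= n - 1)].astype(float)
            out[r] = float(np.sum(k * (n - k)) / denom)
        return out


# ---------------------------------------------------------------------------
# genealogy machinery


def _waiting_time(rng, base_rate: float, t0: float, dem: DemographyModel) -> float:
    """Time to the next event at hazard base_rate/(ratio*f), piecewise in t."""
    E = rng.exponential()
    f = dem.inheritance_factor
    t = t0
    epochs = dem.epochs
    for i, (start, ratio) in enumerate(epochs):
        end = epochs[i + 1][0] if i + 1 < len(epochs) else np.inf
        if end <= t:
            continue
        rate = base_rate / (ratio * f)
        span = end - max(t, start)
        hazard = rate * span
        if E <= hazard or not np.isfinite(end):
            return max(t, start) + E / rate - t0
        E -= hazard
        t = end
    raise RuntimeError("unreachable: final epoch is unbounded")


def _waiting_time_vec(
    E: np.ndarray, base_rate: float, t0: np.ndarray, dem: DemographyModel
) -> np.ndarray:
    """Vectorized piecewise-epoch waiting time (same model as _waiting_time)."""
    f = dem.inheritance_factor
    epochs = dem.epochs
    out = np.empty_like(E)
    remaining = E.copy()
    cur = t0.astype(float).copy()
    done = np.zeros(E.shape, dtype=bool)
    for i, (start, ratio) in enumerate(epochs):
        end = epochs[i + 1][0] if i + 1 < len(epochs) else np.inf
        rate = base_rate / (ratio * f)
        m = ~done & (cur < end)
        if not m.any():
            continue
        idx = np.nonzero(m)
        tt = np.maximum(cur[m], start)
        hazard = rate * (end - tt)
        fits = remaining[m] <= hazard
        if np.isinf(end):
            fits = np.ones_like(fits)
        sel = tuple(a[fits] for a in idx)
        out[sel] = tt[fits] + remaining[m][fits] / rate - t0[sel]
        done[sel] = True
        rest = tuple(a[~fits] for a in idx)
        remaining[rest] -= hazard[~fits]
        cur[rest] = end
    return out


def _batch_interval_times(
    rng, n: int, dem: DemographyModel, attempts: int, W: int
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-coalescence times for (attempts x W) independent genealogies.

    Returns (times with shape (attempts, W, n-1), total tree lengths with
    shape (attempts, W)).
    """
    ks = np.arange(n, 1, -1)
    shape = (attempts, W)
    if dem.is_snm and dem.inheritance_factor == 1.0:
        times = rng.exponential(1.0 / (ks * (ks - 1)), size=shape + (n - 1,))
    else:
        times = np.empty(shape + (n - 1,))
        t = np.zeros(shape)
        for i, k in enumerate(ks):
            E = rng.exponential(size=shape)
            dt = _waiting_time_vec(E, float(k * (k - 1)), t, dem)
            times[..., i] = dt
            t += dt
    lengths = times @ ks.astype(float)
    return times, lengths


def _coalescent_intervals(
    rng, n: int, dem: DemographyModel, t_start: float = 0.0
) -> tuple[list[tuple[int, float]], float, float]:
    """Inter-coalescence intervals [(k, dt)...], total tree length, TMRCA."""
    intervals = []
    t = t_start
    length = 0.0
    if dem.is_snm and dem.inheritance_factor == 1.0:
        ks = np.arange(n, 1, -1)
        dts = rng.exponential(1.0 / (ks * (ks - 1)))
        for k, dt in zip(ks, dts):
            intervals.append((int(k), float(dt)))
            length += k * dt
            t += dt
    else:
        for k in range(n, 1, -1):
            dt = _waiting_time(rng, float(k * (k - 1)), t, dem)
            intervals.append((k, dt))
            length += k * dt
            t += dt
    return intervals, float(length), float(t)


def _attach_topology(
    rng, intervals: Sequence[tuple[int, float]], active: list[tuple[int, float]], t0: float
) -> tuple[list[tuple[int, float]], list[tuple[int, float]], float]:
    """Random joins for the given intervals.

    active: list of (leaf bitmask, birth time). Returns (branches as
    (mask, length), remaining active lineages, final time).
    """
    branches = []
    t = t0
    for _, dt in intervals:
        t += dt
        i = int(rng.integers(len(active)))
        j = int(rng.integers(len(active) - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        mj, bj = active.pop(j)
        mi, bi = active.pop(i)
        branches.append((mi, t - bi))
        branches.append((mj, t - bj))
        active.append((mi | mj, t))
    return branches, active, t


def _neutral_genealogy(rng, n: int, dem: DemographyModel):
    """Branches (leaf-mask, length) of one neutral genealogy + (length, tmrca)."""
    intervals, length, tmrca = _coalescent_intervals(rng, n, dem)
    active = [(1 << i, 0.0) for i in range(n)]
    branches, _, _ = _attach_topology(rng, intervals, active, 0.0)
    return branches, length, tmrca


def _sweep_genealogy(
    rng, n: int, dem: DemographyModel, p_esc: float, t_sweep: float = 0.0
):
    """Genealogy with an instantaneous partial sweep at time t_sweep.

    Below the sweep the process is neutral; at t_sweep every surviving
    lineage escapes independently with probability p_esc; all non-escaping
    lineages coalesce into one; the process continues neutrally above.
    """
    branches: list[tuple[int, float]] = []
    active = [(1 << i, 0.0) for i in range(n)]
    t = 0.0
    if t_sweep > 0.0:
        # neutral phase capped at the sweep time
        while len(active) > 1:
            k = len(active)
            dt = _waiting_time(rng, float(k * (k - 1)), t, dem)
            if t + dt >= t_sweep:
                break
            b, active, t = _attach_topology(rng, [(k, dt)], active, t)
            branches.extend(b)
        # advance every surviving lineage to the sweep time
        t = t_sweep
    if len(active) > 1:
        esc = rng.random(len(active)) < p_esc
        swept = [i for i, e in enumerate(esc) if not e]
        if len(swept) >= 2:
            mask = 0
            for i in swept:
                m, b = active[i]
                branches.append((m, t - b))
                mask |= m
            active = [a for i, a in enumerate(active) if i not in set(swept)]
            active.append((mask, t))
    if len(active) > 1:
        k0 = len(active)
        intervals = []
        tt = t
        for k in range(k0, 1, -1):
            dt = _waiting_time(rng, float(k * (k - 1)), tt, dem)
            intervals.append((k, dt))
            tt += dt
        b, active, t = _attach_topology(rng, intervals, active, t)
        branches.extend(b)
    length = float(sum(bl for _, bl in branches))
    return branches, length, t


def _place_mutations_masks(rng, branches, S: int) -> list[int]:
    """Leaf masks of exactly S mutations placed multinomially by length."""
    p = np.array([bl for _, bl in branches], dtype=float)
    p /= p.sum()
    idx = rng.choice(len(branches), size=S, p=p)
    return [branches[i][0] for i in idx]


def _finite_sites_counts(
    rng, n: int, site_ids: np.ndarray, masks: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve multiple hits on discrete sites under JC symmetry.

    Returns (unique site ids, derived counts; -1 marks a site left with more
    than two alleles). Back mutations can erase segregation (count 0, site
    dropped).
    """
    out_sites = []
    out_counts = []
    order = np.argsort(site_ids, kind="stable")
    site_ids = site_ids[order]
    masks = [masks[i] for i in order]
    i = 0
    while i < len(site_ids):
        j = i
        while j < len(site_ids) and site_ids[j] == site_ids[i]:
            j += 1
        group = masks[i:j]
        if len(group) == 1:
            out_sites.append(site_ids[i])
            out_counts.append(group[0].bit_count())
        else:
            # ancestors first (masks on one tree are nested or disjoint)
            group = sorted(group, key=lambda m: -m.bit_count())
            base_of = {}
            bases = ["A", "C", "G", "T"]
            anc = "A"
            assigned = []
            for gi, m in enumerate(group):
                ctx = anc
                for pj in range(gi - 1, -1, -1):
                    if group[pj] & m == m:  # strict or equal superset
                        ctx = assigned[pj]
                        break
                choices = [b for b in bases if b != ctx]
                assigned.append(choices[int(rng.integers(3))])
            leaf_base = []
            for leaf in range(n):
                b = anc
                best = None
                for gi, m in enumerate(group):
                    if m >> leaf & 1:
                        if best is None or m.bit_count() < group[best].bit_count():
                            best = gi
                if best is not None:
                    b = assigned[best]
                leaf_base.append(b)
            alleles = set(leaf_base)
            if len(alleles) == 1:
                pass  # back mutation erased segregation
            elif len(alleles) == 2:
                derived = sum(1 for b in leaf_base if b != anc)
                if 0 < derived < n or anc not in alleles:
                    if anc not in alleles:
                        # ancestral state lost: derived count ill-defined -> flag
                        out_sites.append(site_ids[i])
                        out_counts.append(-1)
                    else:
                        out_sites.append(site_ids[i])
                        out_counts.append(derived)
            else:
                out_sites.append(site_ids[i])
                out_counts.append(-1)
        i = j
    return np.array(out_sites, dtype=float), np.array(out_counts, dtype=int)


# ---------------------------------------------------------------------------
# public simulation entry points


def _draw_theta(rng, config: SimulationConfig) -> float:
    if config.theta_prior is not None:
        lo, hi = config.theta_prior
        return float(rng.uniform(lo, hi))
    if config.theta is None:
        raise ValueError("config needs theta or theta_prior")
    return float(config.theta)


def _one_replicate(rng, config, dem, theta_site, genealogy_fn):
    """Simulate all windows of one replicate; returns pos, counts, len, tmrca."""
    pos_all, cnt_all = [], []
    total_len = 0.0
    tmrcas = []
    for start, width in config.windows():
        branches, length, tmrca = genealogy_fn(rng, start + width / 2.0)
        total_len += length
        tmrcas.append(tmrca)
        if length <= 0 or theta_site <= 0:
            continue
        S = rng.poisson(theta_site * width * length)
        if S == 0:
            continue
        masks = _place_mutations_masks(rng, branches, S)
        if config.finite_sites:
            sites = start + rng.integers(0, max(1, int(round(width))), size=S)
            s_ids, cnts = _finite_sites_counts(rng, config.n, sites, masks)
            keep = cnts != 0
            pos_all.append(s_ids[keep])
            cnt_all.append(cnts[keep])
        else:
            ks = np.array([m.bit_count() for m in masks], dtype=int)
            keep = (ks >= 1) & (ks <= config.n - 1)
            pos = start + rng.random(S) * width
            pos_all.append(pos[keep])
            cnt_all.append(ks[keep])
    if pos_all:
        pos = np.concatenate(pos_all)
        cnt = np.concatenate(cnt_all)
        order = np.argsort(pos)
        return pos[order], cnt[order], total_len, float(np.mean(tmrcas))
    return np.empty(0), np.empty(0, dtype=int), total_len, float(np.mean(tmrcas))


def simulate_neutral(
    config: SimulationConfig,
    demography: Optional[DemographyModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationReplicateSet:
    """Neutral replicates under the given demography (SNM by default)."""
    dem = demography or DemographyModel.snm()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    positions, counts = [], []
    thetas = np.empty(config.reps)
    lens = np.empty(config.reps)
    tmrcas = np.empty(config.reps)

    def genealogy(r, _mid):
        return _neutral_genealogy(r, config.n, dem)

    for rep in range(config.reps):
        theta = _draw_theta(rng, config)
        pos, cnt, tl, tm = _one_replicate(rng, config, dem, theta, genealogy)
        positions.append(pos)
        counts.append(cnt)
        thetas[rep] = theta
        lens[rep] = tl
        tmrcas[rep] = tm
    return SimulationReplicateSet(
        config=config,
        demography=dem,
        positions=positions,
        counts=counts,
        thetas=thetas,
        tree_lengths=lens,
        tmrcas=tmrcas,
        seed=config.seed,
    )


def simulate_fixed_S(
    config: SimulationConfig,
    demography: Optional[DemographyModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationReplicateSet:
    """Fixed-S rejection sampling with a uniform theta prior.

    Each accepted replicate has exactly fixed_S segregating mutations placed
    multinomially on the genealogy; theta is drawn fresh per attempt and the
    acceptance rate is recorded. Aborts when the acceptance rate falls below
    config.min_acceptance.
    """
    if config.fixed_S is None:
        raise ValueError("config.fixed_S must be set")
    if config.theta_prior is None:
        raise ValueError("fixed-S conditioning requires a theta prior")
    dem = demography or DemographyModel.snm()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    target = int(config.fixed_S)
    windows = config.windows()
    W = len(windows)
    widths = np.array([w for _, w in windows])
    starts = np.array([s for s, _ in windows])
    ks = np.arange(config.n, 1, -1)
    lo, hi = config.theta_prior

    positions, counts = [], []
    thetas, lens, tmrcas = [], [], []
    attempts = 0
    accepted = 0
    chunk = max(64, min(4096, 2 ** 22 // max(1, W * (config.n - 1))))

    while accepted < config.reps:
        # vectorized candidate stage: interval times and tree lengths only
        times, lengths = _batch_interval_times(rng, config.n, dem, chunk, W)
        th = rng.uniform(lo, hi, size=chunk)
        weighted = lengths @ widths  # sum_w width_w * treelen_w
        S = rng.poisson(th * weighted)
        attempts += chunk
        for i in np.nonzero(S == target)[0]:
            if accepted >= config.reps:
                break
            # topology + mutation placement only for accepted candidates
            wl = th[i] * widths * lengths[i]
            alloc = rng.multinomial(target, wl / wl.sum())
            pos_all, cnt_all = [], []
            for w in range(W):
                if alloc[w] == 0:
                    continue
                intervals = [(int(k), float(t)) for k, t in zip(ks, times[i, w])]
                active = [(1 << b, 0.0) for b in range(config.n)]
                branches, _, _ = _attach_topology(rng, intervals, active, 0.0)
                masks = _place_mutations_masks(rng, branches, int(alloc[w]))
                kcnt = np.array([m.bit_count() for m in masks], dtype=int)
                pos_all.append(starts[w] + rng.random(int(alloc[w])) * widths[w])
                cnt_all.append(kcnt)
            pos = np.concatenate(pos_all) if pos_all else np.empty(0)
            cnt = np.concatenate(cnt_all) if cnt_all else np.empty(0, dtype=int)
            order = np.argsort(pos)
            positions.append(pos[order])
            counts.append(cnt[order])
            thetas.append(float(th[i]))
            lens.append(float(lengths[i].sum()))
            tmrcas.append(float(times[i].sum(axis=-1).mean()))
            accepted += 1
        if attempts >= 2e5 and accepted / attempts < config.min_acceptance:
            raise RuntimeError(
                f"fixed-S acceptance rate {accepted}/{attempts} = "
                f"{accepted / attempts:.2e} below floor {config.min_acceptance}; "
                f"target S={target} may be inconsistent with the theta prior "
                f"{config.theta_prior} at L={config.L}"
            )
    return SimulationReplicateSet(
        config=config,
        demography=dem,
        positions=positions,
        counts=counts,
        thetas=np.array(thetas),
        tree_lengths=np.array(lens),
        tmrcas=np.array(tmrcas),
        acceptance_rate=accepted / attempts,
        seed=config.seed,
    )


def simulate_sweep(
    config: SimulationConfig,
    alpha: Optional[float] = None,
    X: Optional[float] = None,
    p_esc: Optional[float] = None,
    time_since_sweep: float = 0.0,
    epsilon: float = 1e-6,
    demography: Optional[DemographyModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationReplicateSet:
    """Replicates under an instantaneous partial selective sweep.

    Either give (alpha, X) — the escape probability then varies with each
    window's recombination distance from X — or a constant p_esc for a
    single matched escape probability (oracle experiments).
    """
    dem = demography or DemographyModel.snm()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if p_esc is None:
        if alpha is None or X is None:
            raise ValueError("need (alpha, X) or p_esc")
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 <= X < config.L):
            raise ValueError("X must lie in [0, L)")
        from sweepkit.sweepscan import escape_probability

        def p_of(mid):
            return escape_probability(
                abs(mid - X), config.rho_per_site, alpha, epsilon
            )
    else:
        if not (0.0 <= p_esc <= 1.0):
            raise ValueError("p_esc must be in [0, 1]")

        def p_of(mid):
            return p_esc

    positions, counts = [], []
    thetas = np.empty(config.reps)
    lens = np.empty(config.reps)
    tmrcas = np.empty(config.reps)

    def genealogy(r, mid):
        return _sweep_genealogy(r, config.n, dem, p_of(mid), time_since_sweep)

    for rep in range(config.reps):
        theta = _draw_theta(rng, config)
        pos, cnt, tl, tm = _one_replicate(rng, config, dem, theta, genealogy)
        positions.append(pos)
        counts.append(cnt)
        thetas[rep] = theta
        lens[rep] = tl
        tmrcas[rep] = tm
    return SimulationReplicateSet(
        config=config,
        demography=dem,
        positions=positions,
        counts=counts,
        thetas=thetas,
        tree_lengths=lens,
        tmrcas=tmrcas,
        seed=config.seed,
    )


def write_ms(reps_set: SimulationReplicateSet, fh) -> None:
    """ms-compatible segregating-sites block (positions scaled to [0,1)).

    Haplotype rows are reconstructed as derived-count-consistent 0/1 columns
    (an arbitrary assignment of carriers; per-site counts, not linkage, are
    what downstream consumers of this block read).
    """
    cfg = reps_set.config
    fh.write(f"sweepkit {cfg.n} {reps_set.reps}\n{reps_set.seed}\n")
    for r in range(reps_set.reps):
        pos = reps_set.positions[r]
        cnt = reps_set.counts[r]
        keep = (cnt >= 1) & (cnt <= cfg.n - 1)
        pos, cnt = pos[keep], cnt[keep].astype(int)
        fh.write("\n//\n")
        fh.write(f"segsites: {len(pos)}\n")
        if len(pos) == 0:
            continue
        fh.write("positions: " + " ".join(f"{p / cfg.L:.5f}" for p in pos) + "\n")
        hap = np.zeros((cfg.n, len(pos)), dtype=int)
        for j, k in enumerate(cnt):
            hap[:k, j] = 1
        for row in hap:
            fh.write("".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# empirical p-values


@dataclass
class PValue:
    """Empirical probability, possibly only bounded above by 1/reps."""

    value: float
    reps: int
    bound: bool = False

    def __str__(self) -> str:
        if self.bound:
            return f"<{1.0 / self.reps:.3f}"
        return f"{self.value:.3f}"

    def __float__(self) -> float:
        return self.value


def empirical_pvalue(stat_obs: float, replicate_stats, tail: str = "lower") -> PValue:
    """Empirical tail probability of stat_obs among simulated replicates.

    lower: P(sim <= obs); upper: P(sim >= obs). When no replicate is as
    extreme the result is the bound '<1/reps'.
    """
    sims = np.asarray(replicate_stats, dtype=float)
    sims = sims[np.isfinite(sims)]
    reps = len(sims)
    if reps == 0:
        raise ValueError("need at least one replicate statistic")
    if tail == "lower":
        count = int(np.sum(sims <= stat_obs))
    elif tail == "upper":
        count = int(np.sum(sims >= stat_obs))
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    if count == 0:
        return PValue(value=1.0 / reps, reps=reps, bound=True)
    return PValue(value=count / reps, reps=reps, bound=False)
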