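"""Synthetic tagmentation data generator.

Emulates the statistical structure of CUT&Tag libraries that the rest of
the package analyses:

* **accessibility-driven background** — untargeted Tn5 tagmentation lands
  preferentially at nucleosome-depleted, open-chromatin sites;
* **targeted capture** — antibody- or ligand-directed tagmentation
  concentrated on the subset of accessible sites carrying a true G4;
* **PCR duplication** — each unique molecule receives a Poisson number of
  sequencing draws, and molecules never drawn are unobserved, so the
  zero-truncated Poisson complexity estimator is exactly correct on
  simulated libraries (parameter-recovery tests rely on this).

No sequence content, alignment or nucleosome positioning is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fragments import FragmentLibrary
from .intervals import GenomeLayout, IntervalSet, PlacementError


class ConfigurationError(ValueError):
    """Raised for contradictory simulation settings."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated genome/site-map/library scenario.

    The defaults are the package's standard study conditions: a targeted
    CUT&Tag library in which 60% of molecules derive from G4-directed
    tagmentation and the remainder from accessibility background, sequenced
    to a mean per-molecule depth of 2.
    """

    n_accessible: int = 300
    g4_fraction: float = 0.25
    p_target: float = 0.6
    p_accessible_bg: float = 0.7
    n_unique_molecules: int = 30_000
    mean_depth_per_molecule: float = 2.0
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 60.0
    accessible_width: int = 800
    g4_width: int = 150
    jitter_sd: float = 150.0
    weight_sigma: float = 1.5
    amplification_bias_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("g4_fraction", "p_target", "p_accessible_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth_per_molecule <= 0:
            raise ConfigurationError("mean_depth_per_molecule must be > 0")
        if self.n_unique_molecules < 1:
            raise ConfigurationError("n_unique_molecules must be >= 1")
        if self.n_accessible < 0:
            raise ConfigurationError("n_accessible must be >= 0")


@dataclass(frozen=True)
class SiteMap:
    """Accessible chromatin sites, their weights, and the true-G4 subset."""

    accessible: IntervalSet
    g4_true: IntervalSet
    site_weights: np.ndarray  # aligned with accessible rows; sums to 1
    g4_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self):
        if len(self.accessible) != len(self.site_weights):
            raise ValueError("one weight per accessible site required")
        if len(self.site_weights) and not np.isclose(self.site_weights.sum(), 1.0):
            raise ValueError("site weights must sum to 1")


MIN_FRAGMENT_LENGTH = 30


def default_layout(
    n_chroms: int = 3, chrom_length: int = 10_000_000, blacklist_frac: float = 0.01,
    blacklist_block: int = 10_000,
) -> GenomeLayout:
    """Desk-scale synthetic genome: 3 x 10 Mb, 1% blacklist in 10 kb blocks."""
    chroms = tuple((f"chr{i + 1}", chrom_length) for i in range(n_chroms))
    n_blocks = max(1, int(round(blacklist_frac * chrom_length / blacklist_block)))
    rows = []
    for name, length in chroms:
        stride = length // n_blocks
        for k in range(n_blocks):
            s = k * stride + (stride - blacklist_block) // 2
            rows.append((name, s, s + blacklist_block))
    return GenomeLayout(chroms, IntervalSet.from_records(rows))


def simulate_genome(
    config: SimulationConfig, layout: GenomeLayout | None = None
) -> tuple[GenomeLayout, SiteMap]:
    """Place accessible sites outside the blacklist and flag the G4 subset.

    Sites are non-overlapping, uniformly placed on non-blacklist sequence.
    ``round(g4_fraction * n_accessible)`` sites are flagged as true G4s,
    sampled without replacement proportionally to their accessibility weight
    (G4s sit in the most accessible chromatin), with each G4 interval
    centered inside its accessible site.
    """
    if layout is None:
        layout = default_layout()
    rng = np.random.default_rng(config.seed)
    width = config.accessible_width
    segs = [(c, s, e) for c, s, e in layout.allowed_segments() if e - s >= width]
    if not segs:
        raise PlacementError("no non-blacklist segment can hold an accessible site")
    seg_room = np.array([e - s - width + 1 for _, s, e in segs], dtype=float)
    seg_prob = seg_room / seg_room.sum()

    placed: dict[str, list[tuple[int, int]]] = {}
    rows = []
    tries = 0
    max_tries = 200 * max(config.n_accessible, 1)
    while len(rows) < config.n_accessible:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(rows)} of {config.n_accessible} accessible"
                " sites without overlap; genome too small"
            )
        tries += 1
        si = rng.choice(len(segs), p=seg_prob)
        chrom, seg_s, seg_e = segs[si]
        s = int(rng.integers(seg_s, seg_e - width + 1))
        e = s + width
        if any(ps < e and pe > s for ps, pe in placed.get(chrom, ())):
            continue
        placed.setdefault(chrom, []).append((s, e))
        rows.append((chrom, s, e))

    accessible = IntervalSet.from_records(rows)
    n = len(accessible)
    # weights are i.i.d., so drawing them against the sorted site order is
    # distributionally identical and keeps everything deterministic
    raw_w = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    weights = raw_w / raw_w.sum() if n else raw_w

    n_g4 = int(round(config.g4_fraction * n))
    if n_g4 > 0:
        g4_idx = np.sort(rng.choice(n, size=n_g4, replace=False, p=weights))
    else:
        g4_idx = np.array([], dtype=np.int64)
    g4_rows = []
    acc = accessible.df
    gw = min(config.g4_width, width)
    for i in g4_idx:
        s, e = int(acc.loc[i, "start"]), int(acc.loc[i, "end"])
        mid = (s + e) // 2
        g4_rows.append((acc.loc[i, "chrom"], mid - gw // 2, mid - gw // 2 + gw))
    sites = SiteMap(accessible, IntervalSet.from_records(g4_rows), weights, g4_idx)
    return layout, sites


def _draw_uniform_positions(rng, layout: GenomeLayout, n: int):
    """Uniform positions on non-blacklist sequence -> (chrom codes, pos)."""
    segs = layout.allowed_segments()
    lens = np.array([e - s for _, s, e in segs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])
    u = rng.integers(0, cum[-1], size=n)
    si = np.searchsorted(cum, u, side="right") - 1
    offs = u - cum[si]
    chroms = np.array([c for c, _, _ in segs])
    starts = np.array([s for _, s, _ in segs], dtype=np.int64)
    return chroms[si], starts[si] + offs


def simulate_library(
    layout: GenomeLayout,
    sites: SiteMap,
    config: SimulationConfig,
    library_id: str = "lib",
) -> FragmentLibrary:
    """Draw a fragment library as a three-way placement mixture.

    Each of ``n_unique_molecules`` molecules is, with probability
    ``p_target``, centered (with Gaussian jitter) on a true-G4 site; else,
    with probability ``p_accessible_bg``, centered on an accessible site
    drawn by accessibility weight; else placed uniformly on non-blacklist
    sequence.  Each molecule then receives Poisson(lambda) sequencing draws
    and molecules with zero draws are dropped.
    """
    if config.p_target > 0 and len(sites.g4_true) == 0:
        raise ConfigurationError("p_target > 0 requires a non-empty g4_true set")
    rng = np.random.default_rng(config.seed)
    n = config.n_unique_molecules
    sizes = layout.chrom_sizes

    u1 = rng.random(n)
    u2 = rng.random(n)
    is_target = u1 < config.p_target
    is_acc = ~is_target & (u2 < config.p_accessible_bg)
    is_uni = ~is_target & ~is_acc

    chrom = np.empty(n, dtype=object)
    center = np.zeros(n, dtype=np.int64)

    acc_df = sites.accessible.df
    acc_chrom = acc_df["chrom"].to_numpy()
    acc_mid = ((acc_df["start"] + acc_df["end"]) // 2).to_numpy()

    nt = int(is_target.sum())
    if nt:
        g4w = sites.site_weights[sites.g4_indices]
        g4w = g4w / g4w.sum()
        pick = rng.choice(len(sites.g4_indices), size=nt, p=g4w)
        site = sites.g4_indices[pick]
        jit = np.rint(rng.normal(0.0, config.jitter_sd, size=nt)).astype(np.int64)
        chrom[is_target] = acc_chrom[site]
        center[is_target] = acc_mid[site] + jit

    na = int(is_acc.sum())
    if na:
        if len(acc_df) == 0:
            raise ConfigurationError("p_accessible_bg > 0 requires accessible sites")
        site = rng.choice(len(acc_df), size=na, p=sites.site_weights)
        jit = np.rint(rng.normal(0.0, config.jitter_sd, size=na)).astype(np.int64)
        chrom[is_acc] = acc_chrom[site]
        center[is_acc] = acc_mid[site] + jit

    nu = int(is_uni.sum())
    if nu:
        uc, up = _draw_uniform_positions(rng, layout, nu)
        chrom[is_uni] = uc
        center[is_uni] = up

    length = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n)
    ).astype(np.int64)
    length = np.maximum(length, MIN_FRAGMENT_LENGTH)

    if config.amplification_bias_sd > 0:
        sd = config.amplification_bias_sd
        lam = config.mean_depth_per_molecule * rng.lognormal(-sd * sd / 2.0, sd, size=n)
    else:
        lam = np.full(n, config.mean_depth_per_molecule)
    copies = rng.poisson(lam)

    chrom_len = np.array([sizes[str(c)] for c in chrom], dtype=np.int64)
    start = center - length // 2
    end = start + length
    # clip to chromosome bounds while preserving length where possible
    shift = np.maximum(-start, 0) - np.maximum(end - chrom_len, 0)
    start = start + shift
    end = end + shift
    start = np.maximum(start, 0)
    end = np.minimum(end, chrom_len)

    keep = copies > 0
    frame = pd.DataFrame(
        {"chrom": chrom[keep], "start": start[keep], "end": end[keep],
         "copy_count": copies[keep]}
    )
    return FragmentLibrary(
        frame, library_id=library_id, targeted=config.p_target > 0, deduplicated=False
    )


def library_config(base: SimulationConfig, **changes) -> SimulationConfig:
    """Derive a per-library config (convenience wrapper over replace)."""
    return replace(base, **changes)
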