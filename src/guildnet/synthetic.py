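"""Synthetic metacommunity generator with planted causes.

Generates a lake-district-like landscape (sites with coordinates and nine
spatially autocorrelated environmental covariates), species whose occurrence
is governed by logistic combinations of a baseline, a Gaussian environmental
niche, a dispersal penalty and pairwise conditional interactions, and count
tables with uneven sequencing depth.  Every run returns a ground-truth table
of planted per-pair causes so downstream inference can be benchmarked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: The nine environmental covariates carried by every site, with the value
#: range each is generated in (units follow limnological convention).
ENV_VARS = ["pH", "DOC", "NO3", "TP", "SRP", "DRSi", "SO4", "RWT", "altitude"]

ENV_RANGES = {
    "pH": (4.5, 9.5),        # unitless
    "DOC": (0.2, 6.0),       # mg/L
    "NO3": (0.1, 30.0),      # uM
    "TP": (1.0, 30.0),       # ug/L
    "SRP": (0.5, 10.0),      # ug/L
    "DRSi": (1.0, 60.0),     # uM
    "SO4": (5.0, 120.0),     # uM
    "RWT": (1.0, 1000.0),    # days
    "altitude": (1500.0, 3000.0),  # m
}

#: Relative weight of the linear spatial trend vs the smoothed noise for each
#: covariate; altitude and pH are strongly structured, nutrients less so.
_TREND_WEIGHT = {
    "pH": 0.6, "DOC": 0.4, "NO3": 0.4, "TP": 0.35, "SRP": 0.35,
    "DRSi": 0.45, "SO4": 0.5, "RWT": 0.3, "altitude": 0.8,
}

_LANDSCAPE_SIZE = 100.0  # side of the square landscape, arbitrary distance units


@dataclass
class SpeciesSpec:
    """Generative parameters of one species.

    Occurrence probability at a site is ``logistic(baseline_logit + niche
    term - dispersal penalty)``.  The niche term is a Gaussian bump of
    amplitude ``niche_height`` centred on ``niche_center`` (shifted so the
    species is favoured inside its niche and disfavoured outside); the
    dispersal penalty is ``(d / dispersal_radius)**2`` with ``d`` the distance
    to ``dispersal_center``.
    """

    species_id: str
    baseline_logit: float = 0.0
    niche_var: str | None = None
    niche_center: float | None = None
    niche_width: float | None = None
    niche_height: float = 6.0
    dispersal_center: tuple[float, float] | None = None
    dispersal_radius: float | None = None
    mean_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.niche_var is not None:
            if self.niche_var not in ENV_VARS:
                raise ValueError(f"unknown niche variable {self.niche_var!r}")
            if self.niche_width is None or self.niche_width <= 0:
                raise ValueError("niche_width must be > 0 when niche_var is set")
        if self.dispersal_center is not None:
            if self.dispersal_radius is None or self.dispersal_radius <= 0:
                raise ValueError("dispersal_radius must be > 0 when dispersal_center is set")
        if self.mean_abundance <= 0:
            raise ValueError("mean_abundance must be > 0")


@dataclass
class InteractionSpec:
    """A planted pairwise interaction.

    ``sign`` is +1 for facilitation, -1 for exclusion; ``strength`` is the
    log-odds shift applied to the later-sampled member at sites where the
    earlier-sampled member is present.  ``strength = 0`` means independence.
    """

    pair: tuple[str, str]
    sign: int
    strength: float

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("interaction pair members must be distinct")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted per-pair cause labels plus the full generative parameters."""

    pair_labels: pd.DataFrame  # columns: taxon_a, taxon_b, cause
    species: list[SpeciesSpec] = field(default_factory=list)
    interactions: list[InteractionSpec] = field(default_factory=list)
    seed: int = 0

    def cause_of(self, a: str, b: str) -> str:
        key = tuple(sorted((a, b)))
        df = self.pair_labels
        hit = df[(df["taxon_a"] == key[0]) & (df["taxon_b"] == key[1])]
        return hit["cause"].iloc[0] if len(hit) else "none"


def generate_sites(n_sites: int, seed: int) -> pd.DataFrame:
    """Generate a site table: coordinates plus nine environmental covariates.

    Coordinates are uniform in a square landscape.  Each covariate is a linear
    spatial trend (random direction) plus Gaussian-bump-smoothed noise, linearly
    rescaled into its declared range, so environment and space are partially
    confounded, as in real lake districts.
    """
    if n_sites < 10:
        raise ValueError(f"n_sites must be >= 10, got {n_sites}")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, _LANDSCAPE_SIZE, size=(n_sites, 2))
    xs, ys = xy[:, 0] / _LANDSCAPE_SIZE, xy[:, 1] / _LANDSCAPE_SIZE

    data = {"x": xy[:, 0], "y": xy[:, 1]}
    n_bumps = 25
    for var in ENV_VARS:
        theta = rng.uniform(0, 2 * np.pi)
        trend = np.cos(theta) * xs + np.sin(theta) * ys
        # smooth autocorrelated noise: a mixture of random Gaussian bumps
        centers = rng.uniform(0, 1, size=(n_bumps, 2))
        amps = rng.normal(size=n_bumps)
        scale = rng.uniform(0.1, 0.3, size=n_bumps)
        d2 = (xs[:, None] - centers[None, :, 0]) ** 2 + (ys[:, None] - centers[None, :, 1]) ** 2
        noise = (amps * np.exp(-d2 / (2 * scale**2))).sum(axis=1)
        noise = (noise - noise.mean()) / (noise.std() + 1e-12)
        trend = (trend - trend.mean()) / (trend.std() + 1e-12)
        w = _TREND_WEIGHT[var]
        raw = w * trend + (1 - w) * noise
        lo, hi = ENV_RANGES[var]
        span = raw.max() - raw.min()
        data[var] = lo + (hi - lo) * (raw - raw.min()) / (span if span > 0 else 1.0)

    index = pd.Index([f"site_{i:03d}" for i in range(n_sites)], name="site_id")
    return pd.DataFrame(data, index=index)


def _occurrence_logits(sites: pd.DataFrame, sp: SpeciesSpec) -> np.ndarray:
    logit = np.full(len(sites), sp.baseline_logit, dtype=float)
    if sp.niche_var is not None:
        z = (sites[sp.niche_var].to_numpy() - sp.niche_center) / sp.niche_width
        # bump shifted so the species is penalised far from its niche centre
        logit += sp.niche_height * (np.exp(-0.5 * z**2) - 0.5)
    if sp.dispersal_center is not None:
        d = np.hypot(
            sites["x"].to_numpy() - sp.dispersal_center[0],
            sites["y"].to_numpy() - sp.dispersal_center[1],
        )
        logit -= (d / sp.dispersal_radius) ** 2
    return logit


def _niches_overlap(a: SpeciesSpec, b: SpeciesSpec) -> bool:
    if a.niche_var is None or a.niche_var != b.niche_var:
        return False
    return abs(a.niche_center - b.niche_center) <= (a.niche_width + b.niche_width)


def _shared_dispersal(a: SpeciesSpec, b: SpeciesSpec) -> bool:
    if a.dispersal_center is None or b.dispersal_center is None:
        return False
    d = np.hypot(
        a.dispersal_center[0] - b.dispersal_center[0],
        a.dispersal_center[1] - b.dispersal_center[1],
    )
    return d <= min(a.dispersal_radius, b.dispersal_radius)


def simulate_occurrence(
    sites: pd.DataFrame,
    species: Sequence[SpeciesSpec],
    interactions: Sequence[InteractionSpec],
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Sample a binary species x site matrix and return it with planted truth.

    Species are sampled sequentially in list order; each interaction shifts the
    logit of its later-listed member at sites where the earlier-listed member
    was realised present (directed generation, undirected truth label).

    Truth labels per unordered pair, priority interaction > dispersal >
    environment: planted interaction pairs; pairs whose dispersal centres lie
    within the smaller radius; pairs sharing a niche variable with overlapping
    niches (centres within the sum of widths).  All other pairs are "none" and
    omitted from the label table.
    """
    ids = [sp.species_id for sp in species]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids")
    order = {sid: i for i, sid in enumerate(ids)}
    for inter in interactions:
        for sid in inter.pair:
            if sid not in order:
                raise ValueError(f"interaction references unknown species {sid!r}")

    rng = np.random.default_rng(seed)
    n = len(sites)
    presence = np.zeros((len(species), n), dtype=np.int8)
    # interactions indexed by their later-sampled (target) member
    by_target: dict[int, list[tuple[int, InteractionSpec]]] = {}
    for inter in interactions:
        i, j = order[inter.pair[0]], order[inter.pair[1]]
        src, tgt = (i, j) if i < j else (j, i)
        by_target.setdefault(tgt, []).append((src, inter))

    for k, sp in enumerate(species):
        logit = _occurrence_logits(sites, sp)
        for src, inter in by_target.get(k, []):
            logit = logit + inter.sign * inter.strength * presence[src]
        p = 1.0 / (1.0 + np.exp(-logit))
        presence[k] = rng.random(n) < p

    occ = pd.DataFrame(presence, index=pd.Index(ids, name="taxon_id"), columns=sites.index)

    labels: dict[tuple[str, str], str] = {}
    spec_by_id = {sp.species_id: sp for sp in species}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sa, sb = spec_by_id[a], spec_by_id[b]
            if _niches_overlap(sa, sb):
                labels[(a, b)] = "environment"
            if _shared_dispersal(sa, sb):
                labels[(a, b)] = "dispersal"
    for inter in interactions:
        key = tuple(sorted(inter.pair))
        if inter.strength > 0:
            labels[key] = "interaction"
    pair_labels = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(labels.items())],
        columns=["taxon_a", "taxon_b", "cause"],
    )
    truth = SyntheticTruth(pair_labels=pair_labels, species=list(species),
                           interactions=list(interactions), seed=seed)
    return occ, truth


def simulate_counts(
    occ: pd.DataFrame,
    species: Sequence[SpeciesSpec],
    depth_range: tuple[int, int],
    seed: int,
) -> pd.DataFrame:
    """Turn an occurrence matrix into a count table with uneven depth.

    Per site the depth is uniform over ``depth_range`` and counts are
    multinomial over the present species with probabilities proportional to
    ``mean_abundance`` times lognormal noise.  Counts are zero exactly where
    the species is absent.
    """
    lo, hi = depth_range
    if lo <= 0 or hi < lo:
        raise ValueError("depth_range must be positive with min <= max")
    rng = np.random.default_rng(seed)
    abund = np.array([sp.mean_abundance for sp in species], dtype=float)
    if len(abund) != occ.shape[0]:
        raise ValueError("species list does not match occurrence matrix rows")
    pres = occ.to_numpy()
    counts = np.zeros_like(pres, dtype=np.int64)
    depths = rng.integers(lo, hi + 1, size=occ.shape[1])
    for j in range(occ.shape[1]):
        mask = pres[:, j] > 0
        if not mask.any():
            warnings.warn(f"site {occ.columns[j]} has no species present; emitting zeros")
            continue
        w = abund[mask] * rng.lognormal(mean=0.0, sigma=0.5, size=int(mask.sum()))
        counts[mask, j] = rng.multinomial(depths[j], w / w.sum())
    return pd.DataFrame(counts, index=occ.index, columns=occ.columns)


def random_community(
    n_species: int,
    sites: pd.DataFrame,
    seed: int,
    frac_niche: float = 0.6,
    frac_dispersal: float = 0.15,
    n_interaction_pairs: int = 10,
    interaction_strength: float = 4.0,
) -> tuple[list[SpeciesSpec], list[InteractionSpec]]:
    """Draw a species pool mirroring a lake-district community.

    Most species carry an environmental niche on a random covariate (environment
    dominates pair structure, as observed in alpine lakes), a minority are
    dispersal limited, and ``n_interaction_pairs`` facilitation/exclusion pairs
    are planted among otherwise neutral species.
    """
    rng = np.random.default_rng(seed)
    species: list[SpeciesSpec] = []
    n_inter_sp = 2 * n_interaction_pairs
    if n_inter_sp > n_species:
        raise ValueError("too many interaction pairs for the species pool")
    n_free = n_species - n_inter_sp
    n_niche = int(round(frac_niche * n_free))
    n_disp = int(round(frac_dispersal * n_free))

    for k in range(n_free):
        sid = f"sp_{k:03d}"
        base = float(rng.normal(-0.5, 0.5))
        if k < n_niche:
            var = ENV_VARS[int(rng.integers(len(ENV_VARS)))]
            lo, hi = ENV_RANGES[var]
            species.append(SpeciesSpec(
                sid, baseline_logit=base, niche_var=var,
                niche_center=float(rng.uniform(lo, hi)),
                niche_width=float(rng.uniform(0.08, 0.25) * (hi - lo)),
                niche_height=float(rng.uniform(3.0, 7.0)),
            ))
        elif k < n_niche + n_disp:
            species.append(SpeciesSpec(
                sid, baseline_logit=base + 1.0,
                dispersal_center=(float(rng.uniform(0, _LANDSCAPE_SIZE)),
                                  float(rng.uniform(0, _LANDSCAPE_SIZE))),
                dispersal_radius=float(rng.uniform(15.0, 40.0)),
            ))
        else:
            species.append(SpeciesSpec(sid, baseline_logit=base))

    interactions: list[InteractionSpec] = []
    for k in range(n_interaction_pairs):
        a = SpeciesSpec(f"int_{2*k:03d}", baseline_logit=float(rng.normal(0.0, 0.3)))
        b = SpeciesSpec(f"int_{2*k+1:03d}", baseline_logit=float(rng.normal(0.0, 0.3)))
        species.extend([a, b])
        sign = 1 if rng.random() < 0.7 else -1
        interactions.append(InteractionSpec((a.species_id, b.species_id), sign,
                                            interaction_strength))

    # abundances: lognormal spread so count tables are realistically skewed
    for sp in species:
        sp.mean_abundance = float(rng.lognormal(0.0, 1.0))
    return species, interactions
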