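"""Synthetic bipartite network collections with a tunable publication effect.

Single networks are drawn from a weighted random bipartite model: each
node carries a log-normal weight (sigma = ``degree_skew``; 0 gives
homogeneous edge probabilities, larger values heavier-tailed expected
degrees), and edge (u, v) appears independently with probability
``connectance * w_u * x_v / (mean(w) * mean(x))`` capped at 1, so the
expected connectance matches the requested one. The giant component is
extracted and the >= 5-per-side filter enforced by bounded resampling.

Collections emulate a corpus whose topology varies both between
"publications" (research teams) and within them: each publication draws
its own connectance / skew / size parameters jittered around the base
config with ``between_sd``, and each of its networks re-jitters those with
``within_sd``. ``between_sd > within_sd`` makes same-publication networks
more topologically similar than cross-publication ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np

from .errors import ConfigError, GenerationError
from .network_io import BipartiteGraph, NetworkRecord

__all__ = [
    "GeneratorConfig",
    "PublicationEffectConfig",
    "generate_network",
    "generate_publication_collection",
]

#: Subgroup labels cycled over publications, for dispersion-by-subgroup output.
_SUBGROUP_CYCLE = ("plant_pollinator", "seed_dispersal", "host_parasite")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a single synthetic bipartite network.

    Defaults describe a mid-sized ecological interaction web: 25 species
    per side, connectance 0.15, moderately heavy-tailed degrees.
    """

    n_sources: int = 25
    n_targets: int = 25
    connectance: float = 0.15
    degree_skew: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1 or self.n_targets < 1:
            raise ConfigError("side sizes must be >= 1")
        if not (0 < self.connectance <= 1):
            raise ConfigError(f"connectance must be in (0, 1], got {self.connectance}")
        if self.degree_skew < 0:
            raise ConfigError(f"degree_skew must be >= 0, got {self.degree_skew}")


@dataclass(frozen=True)
class PublicationEffectConfig:
    """A collection whose topology varies between and within publications.

    ``networks_per_publication`` may be one integer for all publications or
    a sequence of per-publication counts (1 creates a singleton
    publication, exercising the one-network-per-publication grouping).
    """

    n_publications: int = 6
    networks_per_publication: Union[int, tuple[int, ...]] = 10
    between_sd: float = 0.5
    within_sd: float = 0.1
    base: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_publications < 1:
            raise ConfigError("n_publications must be >= 1")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ConfigError("between_sd and within_sd must be >= 0")
        counts = self.per_publication_counts()
        if len(counts) != self.n_publications or any(c < 1 for c in counts):
            raise ConfigError(
                "networks_per_publication must be a positive int or a sequence "
                f"of {self.n_publications} positive ints"
            )

    def per_publication_counts(self) -> tuple[int, ...]:
        if isinstance(self.networks_per_publication, int):
            return (self.networks_per_publication,) * self.n_publications
        return tuple(int(c) for c in self.networks_per_publication)


def _attempt(
    cfg: GeneratorConfig, rng: np.random.Generator, net_id: str
) -> BipartiteGraph | None:
    """One draw from the weighted random bipartite model, or None if empty."""
    if cfg.degree_skew > 0:
        w = rng.lognormal(0.0, cfg.degree_skew, cfg.n_sources)
        x = rng.lognormal(0.0, cfg.degree_skew, cfg.n_targets)
    else:
        w = np.ones(cfg.n_sources)
        x = np.ones(cfg.n_targets)
    P = cfg.connectance * np.outer(w, x) / (w.mean() * x.mean())
    np.clip(P, 0.0, 1.0, out=P)
    A = rng.random((cfg.n_sources, cfg.n_targets)) < P
    if not A.any():
        return None
    sources = tuple(f"s{i:03d}" for i in range(cfg.n_sources))
    targets = tuple(f"t{j:03d}" for j in range(cfg.n_targets))
    edges = frozenset(
        (sources[i], targets[j]) for i, j in zip(*np.nonzero(A))
    )
    # sources are columns (set_b) to mirror the cols_to_rows file convention
    return BipartiteGraph(id=net_id, set_a=targets, set_b=sources, edges=edges)


def generate_network(
    cfg: GeneratorConfig,
    id: str | None = None,
    min_side: int = 5,
    max_retries: int = 100,
) -> BipartiteGraph:
    """Draw one bipartite network passing the giant-component size filter.

    Resamples (up to ``max_retries`` times, advancing a seeded generator)
    until the giant component keeps at least ``min_side`` nodes on each
    side. Fully determined by ``cfg.seed``.
    """
    from .network_io import filter_min_side, giant_component

    net_id = id if id is not None else f"net_seed{cfg.seed}"
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max_retries):
        g = _attempt(cfg, rng, net_id)
        if g is None:
            continue
        g = giant_component(g)
        if filter_min_side(g, min_side):
            return g
    raise GenerationError(
        f"could not generate a network with >= {min_side} nodes per side in "
        f"{max_retries} attempts from config {cfg}"
    )


def _jitter(
    rng: np.random.Generator, base: GeneratorConfig, sd: float
) -> GeneratorConfig:
    """Log-scale jitter of connectance and sizes, additive jitter of skew."""
    c = float(np.clip(base.connectance * np.exp(rng.normal(0.0, sd)), 0.01, 1.0))
    skew = float(max(0.0, base.degree_skew + rng.normal(0.0, sd)))
    smul = float(np.exp(rng.normal(0.0, sd / 2)))
    tmul = float(np.exp(rng.normal(0.0, sd / 2)))
    return replace(
        base,
        connectance=c,
        degree_skew=skew,
        n_sources=max(6, round(base.n_sources * smul)),
        n_targets=max(6, round(base.n_targets * tmul)),
    )


def generate_publication_collection(
    cfg: PublicationEffectConfig,
    min_side: int = 5,
    max_retries: int = 100,
    domain: str = "species_interaction",
) -> list[NetworkRecord]:
    """Generate a labelled corpus with publication-level topology structure.

    Publication p draws parameters by jittering the base config with
    ``between_sd``; each of its networks re-jitters those with
    ``within_sd``. Records carry domain, a subgroup cycled per publication,
    and the publication id. Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[NetworkRecord] = []
    counts = cfg.per_publication_counts()
    for p, n_nets in enumerate(counts):
        pub_cfg = _jitter(rng, cfg.base, cfg.between_sd)
        subgroup = _SUBGROUP_CYCLE[p % len(_SUBGROUP_CYCLE)]
        for k in range(n_nets):
            net_cfg = _jitter(rng, pub_cfg, cfg.within_sd)
            net_cfg = replace(net_cfg, seed=int(rng.integers(2**31)))
            g = generate_network(
                net_cfg,
                id=f"p{p:02d}n{k:02d}",
                min_side=min_side,
                max_retries=max_retries,
            )
            records.append(
                NetworkRecord(
                    graph=g,
                    domain=domain,
                    subgroup=subgroup,
                    publication_id=f"pub{p:02d}",
                )
            )
    return records
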