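"""End-to-end orchestration: load -> orient -> filter -> count -> distance ->
dispersion -> embedding, with provenance and per-stage logging."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import network_io
from .correlation_distance import (
    DGCD6_ORBITS,
    DGCD13_ORBITS,
    DistanceMatrix,
    pairwise_dgcd,
)
from .dispersion_stats import (
    group_mean_pairwise,
    one_per_publication_mean,
    publication_weighted_mean,
)
from .errors import ConfigError, InsufficientDataError, ValidationError
from .graphlet_orbits import count_orbits, write_orbit_counts
from .mds_embedding import embed_mds, plot_embedding
from .network_io import NetworkRecord
from .synthetic_data import (
    GeneratorConfig,
    PublicationEffectConfig,
    generate_publication_collection,
)

logger = logging.getLogger("dgcd")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_corpus", "load_config"]

_VARIANTS = ("dgcd13", "dgcd6", "both")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; serialized into the output dir."""

    networks_dir: str
    metadata_path: str
    output_dir: str
    orientation: str = "cols_to_rows"
    min_side: int = 5
    variant: str = "dgcd13"
    zero_policy: str = "pseudo_node"
    mds_seed: int = 0
    mds_dims: int = 2
    make_plot: bool = True
    focal_domain: str = "species_interaction"

    def __post_init__(self) -> None:
        if self.orientation not in ("cols_to_rows", "rows_to_cols"):
            raise ConfigError(f"bad orientation {self.orientation!r}")
        if self.variant not in _VARIANTS:
            raise ConfigError(f"variant must be one of {_VARIANTS}")
        if self.zero_policy not in ("pseudo_node", "zero_correlation"):
            raise ConfigError(f"bad zero_policy {self.zero_policy!r}")
        if self.min_side < 1:
            raise ConfigError("min_side must be >= 1")
        if self.mds_dims < 1:
            raise ConfigError("mds_dims must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"config {path}: {exc}") from exc


def _variant_subsets(variant: str) -> dict[str, tuple[int, ...]]:
    subsets = {}
    if variant in ("dgcd13", "both"):
        subsets["dgcd13"] = DGCD13_ORBITS
    if variant in ("dgcd6", "both"):
        subsets["dgcd6"] = DGCD6_ORBITS
    return subsets


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns a summary dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))

    # stage 1: load + orient
    net_dir = Path(cfg.networks_dir)
    paths = sorted(net_dir.glob("*.csv"))
    if not paths:
        raise ValidationError(f"no network CSVs found in {net_dir}")
    graphs = [
        network_io.read_incidence_matrix(p, orientation=cfg.orientation)
        for p in paths
    ]
    logger.info("stage=load networks_read=%d", len(graphs))

    # stage 2: metadata reconciliation
    meta = network_io.read_metadata(cfg.metadata_path)
    records = network_io.attach_metadata(graphs, meta)
    dropped_meta = len(graphs) - len(records)
    logger.info("stage=metadata matched=%d dropped=%d", len(records), dropped_meta)

    # stage 3: giant component; stage 4: min-side filter
    surviving: list[NetworkRecord] = []
    dropped_filter = 0
    for r in records:
        g = network_io.giant_component(r.graph)
        if network_io.filter_min_side(g, cfg.min_side):
            surviving.append(
                NetworkRecord(g, r.domain, r.subgroup, r.publication_id)
            )
        else:
            dropped_filter += 1
            logger.warning(
                "network %s dropped: giant component below %d nodes per side",
                r.id,
                cfg.min_side,
            )
    logger.info(
        "stage=filter surviving=%d dropped_min_side=%d", len(surviving), dropped_filter
    )
    if len(surviving) < 2:
        raise InsufficientDataError(
            f"only {len(surviving)} networks survive filtering "
            f"(read {len(graphs)}, no-metadata {dropped_meta}, "
            f"min-side {dropped_filter}); need >= 2"
        )

    # stage 5: orbit counts
    counts_dir = out / "orbit_counts"
    counts_dir.mkdir(exist_ok=True)
    for r in surviving:
        write_orbit_counts(count_orbits(r.graph), counts_dir / f"{r.id}.tsv")
    logger.info("stage=orbits networks=%d", len(surviving))

    # stage 6: pairwise distances per variant
    matrices: dict[str, DistanceMatrix] = {}
    for name, subset in _variant_subsets(cfg.variant).items():
        d = pairwise_dgcd(surviving, subset, cfg.zero_policy)
        d.write_csv(out / f"{name}.csv")
        d.write_long_tsv(out / f"{name}_long.tsv")
        matrices[name] = d
        logger.info("stage=distances variant=%s n_pairs=%d", name, len(d.to_long()))
    primary = matrices.get("dgcd13", next(iter(matrices.values())))

    # stage 7: dispersion reports
    by = {
        "domain": {r.id: r.domain for r in surviving},
        "subgroup": {r.id: r.subgroup for r in surviving},
        "publication": {r.id: r.publication_id for r in surviving},
    }
    summary: dict = {
        "n_networks": len(surviving),
        "dropped_no_metadata": dropped_meta,
        "dropped_min_side": dropped_filter,
        "variant": cfg.variant,
    }
    for key, labels in by.items():
        try:
            report = group_mean_pairwise(primary, labels, group_key=key)
        except ValidationError as exc:
            logger.warning("dispersion by %s unavailable: %s", key, exc)
            continue
        report.write_csv(out / f"dispersion_{key}.csv")
        summary[f"dispersion_{key}"] = report.to_json_dict()
    pub_labels = by["publication"]
    publication_contrast: dict = {}
    try:
        publication_contrast["within_publication_weighted_mean"] = (
            publication_weighted_mean(primary, pub_labels)
        )
    except ValidationError as exc:
        logger.warning("within-publication mean unavailable: %s", exc)
    try:
        publication_contrast["one_per_publication_mean"] = one_per_publication_mean(
            primary, pub_labels
        )
    except ValidationError as exc:
        logger.warning("one-per-publication mean unavailable: %s", exc)
    if publication_contrast:
        summary["publication_contrast"] = publication_contrast
    logger.info("stage=dispersion groups=%s", sorted(by))

    # stage 8: MDS + plot
    emb = embed_mds(primary, dims=cfg.mds_dims, seed=cfg.mds_seed)
    emb.write_csv(out / "mds_coordinates.csv")
    summary["mds_stress"] = emb.stress
    if cfg.make_plot:
        # color by domain when the collection spans several, else by subgroup;
        # the focal domain (species interactions by default) gets triangles
        plot_labels = (
            by["domain"] if len(set(by["domain"].values())) > 1 else by["subgroup"]
        )
        plot_embedding(
            emb,
            labels=plot_labels,
            focal_group=cfg.focal_domain,
            out_png=out / "embedding.png",
            out_svg=out / "embedding.svg",
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("stage=done output_dir=%s", out)
    return summary


def simulate_corpus(
    cfg: PublicationEffectConfig,
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Write a ready-to-run fixture corpus: incidence CSVs, metadata, manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigError(f"output dir {out} is non-empty (use force to overwrite)")
    networks = out / "networks"
    networks.mkdir(parents=True, exist_ok=True)
    records = generate_publication_collection(cfg)
    meta_rows = []
    for r in records:
        network_io.write_incidence_matrix(r.graph, networks / f"{r.id}.csv")
        meta_rows.append(
            network_io.MetadataRow(r.id, r.domain, r.subgroup, r.publication_id)
        )
    network_io.write_metadata(meta_rows, out / "metadata.csv")
    manifest = {
        "n_networks": len(records),
        "config": {
            **asdict(cfg),
            "networks_per_publication": list(cfg.per_publication_counts()),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("stage=simulate networks=%d out=%s", len(records), out)
    return out
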