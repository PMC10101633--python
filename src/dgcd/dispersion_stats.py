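"""Within-group dispersion of pairwise network distances.

Topological heterogeneity of a group of networks is summarized as the mean
(and median) of all within-group pairwise distances. The publication
contrast compares networks created by the same research team ("multiple
networks per publication", summarized by a weighted mean of per-publication
dispersion) with networks that are each the sole product of their
publication.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .correlation_distance import DistanceMatrix
from .errors import ValidationError

logger = logging.getLogger("dgcd")

__all__ = [
    "GroupDispersionReport",
    "group_mean_pairwise",
    "publication_weighted_mean",
    "one_per_publication_mean",
    "between_group_mean",
]

_REPORT_COLUMNS = ["group", "mean_dgcd", "median_dgcd", "n_networks", "n_pairs"]


@dataclass
class GroupDispersionReport:
    """Per-group dispersion table plus the singletons that were excluded."""

    group_key: str
    table: pd.DataFrame  # columns: group, mean_dgcd, median_dgcd, n_networks, n_pairs
    excluded_singletons: tuple[str, ...] = field(default_factory=tuple)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, float_format="%.12g")
        return path

    def to_json_dict(self) -> dict:
        return {
            "group_key": self.group_key,
            "groups": self.table.to_dict(orient="records"),
            "excluded_singletons": list(self.excluded_singletons),
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")
        return path


def _check_labels(d: DistanceMatrix, labels: Mapping[str, str]) -> None:
    missing = [i for i in d.network_ids if i not in labels]
    if missing:
        raise ValidationError(f"unlabeled network ids: {missing[:5]}")


def _within_group_values(
    d: DistanceMatrix, labels: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Upper-triangle distances restricted to same-label pairs, per label."""
    by_label: dict[str, list[int]] = {}
    for i, net in enumerate(d.network_ids):
        by_label.setdefault(labels[net], []).append(i)
    out: dict[str, np.ndarray] = {}
    for label, idxs in by_label.items():
        sub = d.values[np.ix_(idxs, idxs)]
        iu = np.triu_indices(len(idxs), k=1)
        out[label] = sub[iu]
    return out


def group_mean_pairwise(
    d: DistanceMatrix, labels: Mapping[str, str], group_key: str = "group"
) -> GroupDispersionReport:
    """Mean and median within-group pairwise distance, one row per group.

    Groups with a single network have no pairs; they are excluded and
    logged. Rows are ordered by group label.
    """
    _check_labels(d, labels)
    values = _within_group_values(d, labels)
    rows = []
    excluded = []
    counts = {label: v for label, v in values.items()}
    sizes = {label: 0 for label in values}
    for net in d.network_ids:
        sizes[labels[net]] += 1
    for label in sorted(values):
        n = sizes[label]
        pairs = counts[label]
        if n < 2:
            excluded.append(label)
            logger.warning(
                "group %r (%s) has a single network; excluded from dispersion",
                label,
                group_key,
            )
            continue
        rows.append(
            (label, float(pairs.mean()), float(np.median(pairs)), n, len(pairs))
        )
    if not rows:
        raise ValidationError(
            f"no group under {group_key!r} has >= 2 networks; dispersion undefined"
        )
    table = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return GroupDispersionReport(group_key, table, tuple(excluded))


def publication_weighted_mean(
    d: DistanceMatrix,
    pub_labels: Mapping[str, str],
    weight_by: str = "networks",
) -> float:
    """Within-publication dispersion pooled over multi-network publications.

    For each publication p contributing n_p >= 2 networks, let a_p be the
    mean pairwise distance among its networks; returns
    sum(n_p * a_p) / sum(n_p). ``weight_by='pairs'`` swaps the weights for
    C(n_p, 2), the natural alternative for sensitivity analysis.
    """
    if weight_by not in ("networks", "pairs"):
        raise ValidationError("weight_by must be 'networks' or 'pairs'")
    _check_labels(d, pub_labels)
    values = _within_group_values(d, pub_labels)
    num = 0.0
    den = 0.0
    for label, pairs in sorted(values.items()):
        if len(pairs) == 0:
            continue
        n_p = sum(1 for net in d.network_ids if pub_labels[net] == label)
        w = float(n_p) if weight_by == "networks" else float(len(pairs))
        num += w * float(pairs.mean())
        den += w
    if den == 0:
        raise ValidationError("no publication contributes >= 2 networks")
    return num / den


def one_per_publication_mean(
    d: DistanceMatrix, pub_labels: Mapping[str, str]
) -> float:
    """Mean pairwise distance among networks that are sole products of their publication."""
    _check_labels(d, pub_labels)
    sizes: dict[str, int] = {}
    for net in d.network_ids:
        sizes[pub_labels[net]] = sizes.get(pub_labels[net], 0) + 1
    idxs = [
        i for i, net in enumerate(d.network_ids) if sizes[pub_labels[net]] == 1
    ]
    if len(idxs) < 2:
        raise ValidationError(
            "fewer than 2 networks come from single-network publications"
        )
    sub = d.values[np.ix_(idxs, idxs)]
    iu = np.triu_indices(len(idxs), k=1)
    return float(sub[iu].mean())


def between_group_mean(d: DistanceMatrix, labels: Mapping[str, str]) -> float:
    """Mean pairwise distance over pairs whose networks carry different labels."""
    _check_labels(d, labels)
    vals = []
    for i in range(len(d.network_ids)):
        for j in range(i + 1, len(d.network_ids)):
            if labels[d.network_ids[i]] != labels[d.network_ids[j]]:
                vals.append(d.values[i, j])
    if not vals:
        raise ValidationError("no between-group pairs exist")
    return float(np.mean(vals))
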