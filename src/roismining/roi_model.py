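"""Regions of interest and regional synchrony features.

A partition groups electrode sites into named, disjoint regions; for a
10-region partition the subject-level feature vector concatenates

* 10 intraregional synchronies — the mean pairwise synchrony over the
  N_k(N_k-1)/2 unordered channel pairs within each region, and
* 45 interregional synchronies — the mean synchrony over the N_k x N_l
  cross pairs for every region pair k < l in partition order,

for 55 features in all (R + R(R-1)/2 for R regions).  Channels removed as
bad during preprocessing are simply absent from the connectivity matrix;
region means use the surviving channels, and a region that drops below the
minimum raises a degenerate-region error rather than silently producing a
feature from too little data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateRegionError, InvalidParameterError, InvalidPartitionError
from .sync_measures import ConnectivityMatrix, SyncParams

BUNDLED_PARTITIONS = ("partition_I", "partition_II")


@dataclass
class ROIPartition:
    """Named, pairwise-disjoint channel groupings."""

    name: str
    regions: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        if not self.regions:
            raise InvalidPartitionError("partition has no regions")
        seen: dict[str, str] = {}
        labels = set()
        for label, channels in self.regions:
            if label in labels:
                raise InvalidPartitionError(f"duplicate region label {label!r}")
            labels.add(label)
            if not channels:
                raise InvalidPartitionError(f"region {label!r} is empty")
            for ch in channels:
                if ch in seen:
                    raise InvalidPartitionError(
                        f"channel {ch!r} assigned to both {seen[ch]!r} and {label!r}"
                    )
                seen[ch] = label

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_labels(self) -> list[str]:
        return [label for label, _ in self.regions]

    @property
    def n_channels(self) -> int:
        return sum(len(chs) for _, chs in self.regions)

    @property
    def all_channels(self) -> list[str]:
        return [ch for _, chs in self.regions for ch in chs]

    def channels_of(self, region_label: str) -> list[str]:
        for label, channels in self.regions:
            if label == region_label:
                return list(channels)
        raise InvalidParameterError(f"no region labelled {region_label!r}")

    @property
    def n_features(self) -> int:
        r = self.n_regions
        return r + r * (r - 1) // 2


def load_partition(config: str | Path) -> ROIPartition:
    """Load a partition from a YAML config or a bundled name.

    ``config`` may be ``"partition_I"`` / ``"partition_II"`` (the bundled
    defaults) or a path to a YAML file with ``name`` and ``regions`` entries.
    Channels absent from a given waveform are handled at feature time, not
    here.
    """
    if str(config) in BUNDLED_PARTITIONS:
        ref = resources.files("roismining").joinpath(f"data/partitions/{config}.yaml")
        text = ref.read_text()
    else:
        text = Path(config).read_text()
    raw = yaml.safe_load(text)
    try:
        regions = [(str(r["label"]), [str(c) for c in r["channels"]]) for r in raw["regions"]]
        name = str(raw.get("name", Path(str(config)).stem))
    except (KeyError, TypeError) as exc:
        raise InvalidPartitionError(f"malformed partition config {config}: {exc}") from exc
    return ROIPartition(name=name, regions=regions)


@dataclass
class RegionalFeatureVector:
    """Ordered intra- then inter-regional synchrony values for one subject."""

    values: np.ndarray
    names: list[str]
    partition_name: str
    params: SyncParams
    subject_id: str | None = None

    def __len__(self) -> int:
        return len(self.values)


def _present(m: ConnectivityMatrix, channels: list[str]) -> list[int]:
    idx = {lab: i for i, lab in enumerate(m.channel_labels)}
    return [idx[c] for c in channels if c in idx]


def intra_synchrony(m: ConnectivityMatrix, region_channels: list[str]) -> float:
    """Mean synchrony over unordered within-region channel pairs (diagonal excluded)."""
    rows = _present(m, region_channels)
    k = len(rows)
    if k < 2:
        raise DegenerateRegionError(
            f"region needs >= 2 channels present in the matrix, found {k}"
        )
    sub = m.values[np.ix_(rows, rows)]
    iu = np.triu_indices(k, 1)
    return float(sub[iu].mean())


def inter_synchrony(
    m: ConnectivityMatrix, region_k: list[str], region_l: list[str]
) -> float:
    """Mean synchrony over the N_k x N_l cross-region channel pairs."""
    if set(region_k) == set(region_l):
        raise InvalidParameterError("interregional synchrony requires two distinct regions")
    rows = _present(m, region_k)
    cols = _present(m, region_l)
    if not rows or not cols:
        raise DegenerateRegionError("both regions need >= 1 channel present in the matrix")
    return float(m.values[np.ix_(rows, cols)].mean())


def feature_vector(
    m: ConnectivityMatrix, p: ROIPartition, subject_id: str | None = None
) -> RegionalFeatureVector:
    """Concatenate intra then inter synchronies in partition order.

    Ordering: ``[intra(R_1) .. intra(R_R), inter(R_1,R_2), inter(R_1,R_3),
    ..., inter(R_{R-1},R_R)]`` — the inter block enumerates region pairs
    lexicographically (k < l) in the partition's declared order, so vectors
    are comparable across subjects.
    """
    values, names = [], []
    for label, channels in p.regions:
        try:
            values.append(intra_synchrony(m, channels))
        except DegenerateRegionError as exc:
            raise DegenerateRegionError(f"region {label!r}: {exc}") from exc
        names.append(f"intra_{label}")
    for i in range(p.n_regions):
        for j in range(i + 1, p.n_regions):
            lab_i, ch_i = p.regions[i]
            lab_j, ch_j = p.regions[j]
            try:
                values.append(inter_synchrony(m, ch_i, ch_j))
            except DegenerateRegionError as exc:
                raise DegenerateRegionError(f"regions {lab_i!r}/{lab_j!r}: {exc}") from exc
            names.append(f"inter_{lab_i}_{lab_j}")
    return RegionalFeatureVector(
        values=np.asarray(values, dtype=np.float64),
        names=names,
        partition_name=p.name,
        params=m.params,
        subject_id=subject_id,
    )


def feature_frame(
    vectors: list[RegionalFeatureVector],
    groups: list[int] | None = None,
) -> pd.DataFrame:
    """Stack per-subject feature vectors into a table.

    Columns: ``subject``, optionally ``group`` (1 = implanted/positive,
    0 = control/negative), then the named synchrony features.
    """
    if not vectors:
        raise InvalidParameterError("no feature vectors to stack")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise InvalidParameterError("feature vectors have inconsistent columns")
    df = pd.DataFrame(
        [v.values for v in vectors],
        columns=names,
    )
    df.insert(0, "subject", [v.subject_id or f"S{i:02d}" for i, v in enumerate(vectors)])
    if groups is not None:
        df.insert(1, "group", list(groups))
    return df
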