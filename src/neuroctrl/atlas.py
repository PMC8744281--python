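"""234-node parcellation handling and functional-system assignment.

The brain is divided into 234 regions (220 cortical, 14 subcortical — the
bilateral thalamus, caudate, putamen, pallidum, accumbens, hippocampus and
amygdala).  Each cortical region is assigned to one of the seven canonical
resting-state systems (default mode, dorsal attention, frontoparietal
control, limbic, somatomotor, visual, ventral attention) by a purity index:
the fraction of the region's surface vertices carrying the winning system's
label.  Subcortical regions form an eighth system of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Fixed ordering of the seven cortical systems; index breaks purity ties.
CORTICAL_SYSTEMS = ("DMN", "DA", "FCN", "LN", "SMN", "VN", "VA")
SUBCORTICAL = "SUBCORTICAL"
#: All eight systems, subcortical last.
SYSTEMS = CORTICAL_SYSTEMS + (SUBCORTICAL,)

N_NODES = 234
N_CORTICAL = 220
N_SUBCORTICAL = 14

SUBCORTICAL_STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "hippocampus",
    "amygdala",
)


class AtlasError(ValueError):
    """Raised when an atlas or overlap table violates a structural invariant."""


@dataclass(frozen=True)
class NodeInfo:
    node_id: int
    label: str
    hemisphere: str  # "L" or "R"
    compartment: str  # "cortical" or "subcortical"


@dataclass(frozen=True)
class Parcellation:
    """Ordered collection of atlas nodes; row order defines node ids."""

    nodes: tuple[NodeInfo, ...]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        n_sub = sum(1 for nd in self.nodes if nd.compartment == "subcortical")
        labels = [nd.label for nd in self.nodes]
        if len(set(labels)) != n:
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise AtlasError(f"duplicate labels: {dupes}")
        for nd in self.nodes:
            if nd.hemisphere not in ("L", "R"):
                raise AtlasError(
                    f"node {nd.label!r}: unknown hemisphere {nd.hemisphere!r}"
                )
            if nd.compartment not in ("cortical", "subcortical"):
                raise AtlasError(
                    f"node {nd.label!r}: unknown compartment {nd.compartment!r}"
                )
        object.__setattr__(self, "_n_subcortical", n_sub)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [nd.label for nd in self.nodes]

    @property
    def cortical_ids(self) -> list[int]:
        return [nd.node_id for nd in self.nodes if nd.compartment == "cortical"]

    @property
    def subcortical_ids(self) -> list[int]:
        return [nd.node_id for nd in self.nodes if nd.compartment == "subcortical"]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise AtlasError(f"unknown node label {label!r}") from None


@dataclass(frozen=True)
class SystemAssignment:
    """Mapping of every node to one of the eight systems.

    ``system_of[i]`` is the system name for node i; ``purity[i]`` holds the
    purity index for cortical nodes (None for subcortical nodes, whose
    assignment is anatomical, not vote-based).
    """

    system_of: tuple[str, ...]
    purity: tuple[float | None, ...]
    members: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = {s: [] for s in SYSTEMS}
        for i, s in enumerate(self.system_of):
            if s not in SYSTEMS:
                raise AtlasError(f"node {i}: unknown system {s!r}")
            members[s].append(i)
        object.__setattr__(
            self, "members", {s: tuple(v) for s, v in members.items()}
        )
        total = sum(len(v) for v in self.members.values())
        if total != len(self.system_of):
            raise AtlasError("membership lists do not partition the node set")


def load_parcellation(path: str | Path, expected_nodes: int = N_NODES) -> Parcellation:
    """Read an atlas TSV (columns label, hemisphere, compartment).

    Row order defines the 0-based node id.  The default expectation is the
    full 234-node atlas with 220 cortical and 14 subcortical regions; pass
    ``expected_nodes=None`` to accept any size (used by the reduced toy atlas).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"label", "hemisphere", "compartment"}
    if not required.issubset(df.columns):
        raise AtlasError(f"atlas file missing columns {sorted(required - set(df.columns))}")
    nodes = tuple(
        NodeInfo(i, row.label, row.hemisphere, row.compartment)
        for i, row in enumerate(df.itertuples(index=False))
    )
    if expected_nodes is not None and len(nodes) != expected_nodes:
        raise AtlasError(f"expected {expected_nodes} nodes, found {len(nodes)}")
    parc = Parcellation(nodes)
    if expected_nodes == N_NODES:
        n_sub = len(parc.subcortical_ids)
        if n_sub != N_SUBCORTICAL:
            raise AtlasError(
                f"expected {N_SUBCORTICAL} subcortical nodes, found {n_sub}"
            )
    return parc


def load_overlaps(path: str | Path) -> pd.DataFrame:
    """Read a vertex-overlap TSV (columns label, system, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "system": str, "count": int})
    required = {"label", "system", "count"}
    if not required.issubset(df.columns):
        raise AtlasError(f"overlap file missing columns {sorted(required - set(df.columns))}")
    bad = ~df["system"].isin(CORTICAL_SYSTEMS + ("unassigned",))
    if bad.any():
        raise AtlasError(f"unknown system names: {sorted(df.loc[bad, 'system'].unique())}")
    if (df["count"] < 0).any():
        raise AtlasError("negative overlap counts")
    return df


def compute_purity(overlaps: pd.DataFrame, label: str) -> tuple[str, float]:
    """Winning system and purity index for one cortical node.

    Purity = (max overlap count over the seven systems) / (total overlap,
    including any 'unassigned' vertices).  Ties break toward the lowest index
    in the fixed system ordering.
    """
    rows = overlaps[overlaps["label"] == label]
    total = int(rows["count"].sum())
    if total < 1:
        raise AtlasError(f"node {label!r} has no system overlap")
    counts = {s: 0 for s in CORTICAL_SYSTEMS}
    for r in rows.itertuples(index=False):
        if r.system in counts:
            counts[r.system] += int(r.count)
    best = max(CORTICAL_SYSTEMS, key=lambda s: counts[s])  # max is stable: first wins ties
    if counts[best] == 0:
        raise AtlasError(f"node {label!r} has no system overlap")
    return best, counts[best] / total


def assign_systems(parcellation: Parcellation, overlaps: pd.DataFrame) -> SystemAssignment:
    """Assign every node to a system: purity argmax for cortical nodes,
    the eighth (subcortical) system for subcortical nodes."""
    covered = set(overlaps["label"])
    missing = [
        nd.node_id
        for nd in parcellation.nodes
        if nd.compartment == "cortical" and nd.label not in covered
    ]
    if missing:
        raise AtlasError(f"cortical nodes missing from overlap table: {missing}")
    system_of: list[str] = []
    purity: list[float | None] = []
    for nd in parcellation.nodes:
        if nd.compartment == "subcortical":
            system_of.append(SUBCORTICAL)
            purity.append(None)
        else:
            best, p = compute_purity(overlaps, nd.label)
            system_of.append(best)
            purity.append(p)
    return SystemAssignment(tuple(system_of), tuple(purity))


# ---------------------------------------------------------------------------
# Bundled synthetic atlas fixtures


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def default_atlas_path() -> Path:
    """Path of the bundled synthetic 234-node atlas TSV."""
    return _data_path("atlas234_synthetic.tsv")


def default_overlap_path() -> Path:
    return _data_path("overlap234_synthetic.tsv")


def toy_atlas_path() -> Path:
    """Path of the reduced 20-node atlas (16 cortical + 4 subcortical)."""
    return _data_path("atlas20_toy.tsv")


def toy_overlap_path() -> Path:
    return _data_path("overlap20_toy.tsv")


def load_default_atlas() -> tuple[Parcellation, SystemAssignment]:
    parc = load_parcellation(default_atlas_path())
    return parc, assign_systems(parc, load_overlaps(default_overlap_path()))


def load_toy_atlas() -> tuple[Parcellation, SystemAssignment]:
    parc = load_parcellation(toy_atlas_path(), expected_nodes=None)
    return parc, assign_systems(parc, load_overlaps(toy_overlap_path()))
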