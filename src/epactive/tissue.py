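"""Synthetic tissue-excitability fields.

Training fields for the generative model are binary injured/healthy maps
produced by random region growing on the myocardium graph: starting from a
seed node, one of the five nearest non-member neighbors of the current
region is added uniformly at random until the target size is reached.
Injured nodes get excitability 0.5, healthy nodes 0.15, both plus U[0, 0.001]
noise.  Test cases instead place abnormality on AHA segments at graded
severities (0.40 / 0.45 / 0.50) so the test distribution differs from the
training one in both value and shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from epactive.geometry import CardiacGeometry

HEALTHY_THETA = 0.15
INJURED_THETA = 0.5
NOISE_AMPLITUDE = 0.001
SEVERITIES = (0.40, 0.45, 0.50)


@dataclass
class RegionGrowSpec:
    seed_node: int
    target_size: int
    knn: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_size < 1:
            raise ValueError("target_size must be at least 1")
        if self.knn < 1:
            raise ValueError("knn must be at least 1")


@dataclass
class TrainingCorpus:
    fields: np.ndarray  # (n_fields, n_nodes)
    provenance: list[RegionGrowSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fields = np.atleast_2d(np.asarray(self.fields, dtype=float))
        if self.fields.shape[0] < 1:
            raise ValueError("corpus must contain at least one field")
        if np.any(self.fields < 0) or np.any(self.fields > 0.5 + NOISE_AMPLITUDE):
            raise ValueError("corpus fields violate the excitability bounds")

    @property
    def n_fields(self) -> int:
        return self.fields.shape[0]


def region_grow(geom: CardiacGeometry, spec: RegionGrowSpec) -> np.ndarray:
    """Grow a connected injured region by randomized nearest-neighbor accretion.

    At each step the candidate set is the ``spec.knn`` exterior nodes
    closest (Euclidean) to the current region, with ties broken by node
    index; one candidate is drawn uniformly.  Returns a sorted index array
    of exactly ``target_size`` nodes containing ``seed_node``.
    """
    n = geom.n_nodes
    if not 0 <= spec.seed_node < n:
        raise ValueError("seed_node out of range")
    if spec.target_size > n:
        raise ValueError("target_size exceeds node count")
    rng = np.random.default_rng(spec.rng_seed)
    coords = geom.node_coords
    adj = geom.adjacency.tocsr()
    member = np.zeros(n, dtype=bool)
    frontier = np.zeros(n, dtype=bool)  # exterior nodes graph-adjacent to region
    member[spec.seed_node] = True
    frontier[adj[spec.seed_node].nonzero()[1]] = True
    frontier &= ~member
    # min Euclidean distance from every node to the region, updated incrementally
    dist = np.linalg.norm(coords - coords[spec.seed_node], axis=1)
    for _ in range(spec.target_size - 1):
        cand_pool = np.where(frontier)[0]
        if len(cand_pool) == 0:
            raise ValueError(
                "region cannot grow further: target_size exceeds the reachable component"
            )
        order = np.lexsort((cand_pool, dist[cand_pool]))  # distance, then index
        candidates = cand_pool[order[: spec.knn]]
        new = candidates[rng.integers(len(candidates))]
        member[new] = True
        frontier[adj[new].nonzero()[1]] = True
        frontier &= ~member
        dist = np.minimum(dist, np.linalg.norm(coords - coords[new], axis=1))
    return np.sort(np.where(member)[0])


def make_training_field(
    geom: CardiacGeometry, injured: np.ndarray, rng_seed: int = 0
) -> np.ndarray:
    """Binary injured(0.5)/healthy(0.15) field plus U[0, 0.001] noise."""
    injured = np.asarray(injured, dtype=np.int64)
    if len(injured) and (injured.min() < 0 or injured.max() >= geom.n_nodes):
        raise ValueError("injured indices out of range")
    rng = np.random.default_rng(rng_seed)
    theta = np.full(geom.n_nodes, HEALTHY_THETA)
    theta[injured] = INJURED_THETA
    return theta + rng.uniform(0.0, NOISE_AMPLITUDE, size=geom.n_nodes)


def make_aha_test_case(
    geom: CardiacGeometry,
    segments: set[int] | list[int],
    severity: float,
    rng_seed: int = 0,
) -> np.ndarray:
    """Abnormality on whole AHA segments at a graded severity level."""
    segments = set(int(s) for s in segments)
    if not segments:
        raise ValueError("need at least one AHA segment")
    if any(s < 1 or s > 17 for s in segments):
        raise ValueError("AHA segment ids must lie in 1..17")
    if not any(np.isclose(severity, s) for s in SEVERITIES):
        raise ValueError(f"severity must be one of {SEVERITIES}")
    rng = np.random.default_rng(rng_seed)
    abnormal = np.isin(geom.segment_labels, list(segments))
    theta = np.where(abnormal, severity, HEALTHY_THETA)
    return theta + rng.uniform(0.0, NOISE_AMPLITUDE, size=geom.n_nodes)


def generate_corpus(
    geom: CardiacGeometry,
    n_fields: int = 10_000,
    size_range: tuple[float, float] = (0.02, 0.40),
    knn: int = 5,
    seed: int = 0,
) -> TrainingCorpus:
    """Region-growing training corpus; bit-reproducible under ``seed``.

    Region sizes are uniform over ``size_range`` (fractions of the node
    count); seed nodes uniform over the graph.
    """
    rng = np.random.default_rng(seed)
    n = geom.n_nodes
    lo = max(1, int(round(size_range[0] * n)))
    hi = max(lo, int(round(size_range[1] * n)))
    fields = np.empty((n_fields, n), dtype=float)
    provenance: list[RegionGrowSpec] = []
    for i in range(n_fields):
        spec = RegionGrowSpec(
            seed_node=int(rng.integers(n)),
            target_size=int(rng.integers(lo, hi + 1)),
            knn=knn,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        injured = region_grow(geom, spec)
        fields[i] = make_training_field(geom, injured, rng_seed=int(rng.integers(2**31 - 1)))
        provenance.append(spec)
    return TrainingCorpus(fields=fields, provenance=provenance)


def save_corpus(path: str, corpus: TrainingCorpus) -> None:
    import json

    meta = json.dumps(
        [
            {
                "seed_node": s.seed_node,
                "target_size": s.target_size,
                "knn": s.knn,
                "rng_seed": s.rng_seed,
            }
            for s in corpus.provenance
        ]
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("theta", data=corpus.fields)
        f.create_dataset("meta", data=np.bytes_(meta))


def load_corpus(path: str) -> TrainingCorpus:
    import json

    with h5py.File(path, "r") as f:
        fields = f["theta"][:]
        meta = json.loads(bytes(f["meta"][()]).decode())
    provenance = [RegionGrowSpec(**m) for m in meta]
    return TrainingCorpus(fields=fields, provenance=provenance)
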