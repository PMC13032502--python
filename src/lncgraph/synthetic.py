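"""Synthetic input bundles with planted block structure.

The generator emulates the shape of curated lncRNA-disease resources: a
binary association table, bipartite omic link tables (lncRNA-mRNA/RBP/
protein, disease-metabolite/circRNA) and an IS_A disease ontology — but with
a known planted signal. Entities are partitioned into blocks; associations
are dense within matched blocks and sparse across, omic partners are shared
within blocks, and the ontology groups each block under its own subtree.
Every downstream stage can therefore be tested against ground truth without
any download.

The defaults describe the standard study world used throughout the test
suite: 60 lncRNAs x 40 diseases in 4 blocks, within-block association
probability 0.6 against a 0.02 cross-block background, and a 10% symmetric
label-flip noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from lncgraph import io
from lncgraph.types import (
    DISEASE_VIEWS,
    LNCRNA_VIEWS,
    AssociationMatrix,
    Bundle,
    OmicLinkTable,
    OntologyTable,
)

_VIEW_PREFIX = {
    "lncrna_mrna": "M",
    "lncrna_rbp": "R",
    "lncrna_protein": "P",
    "disease_metabolite": "E",
    "disease_circrna": "C",
}


@dataclass
class PlantedWorld:
    """Configuration of a planted-block synthetic world.

    Every probability is in [0, 1] and the planted signal requires
    ``within_block_assoc_prob > cross_block_assoc_prob``.
    """

    n_lncrna: int = 60
    n_disease: int = 40
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.6
    cross_block_assoc_prob: float = 0.02
    partner_pool_sizes: dict[str, int] = field(
        default_factory=lambda: {v: 50 for v in LNCRNA_VIEWS + DISEASE_VIEWS}
    )
    partner_overlap_within_block: float = 0.6
    partner_background_prob: float = 0.05
    noise_flip_prob: float = 0.1
    seed: int = 0

    def validate(self) -> "PlantedWorld":
        if self.n_lncrna < 1 or self.n_disease < 1:
            raise ValueError("world must contain at least one lncRNA and one disease")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if min(self.n_lncrna, self.n_disease) < self.n_blocks:
            raise ValueError(
                "every block needs at least one lncRNA and one disease: "
                f"{self.n_blocks} blocks but only "
                f"{min(self.n_lncrna, self.n_disease)} entities on one side"
            )
        probs = (
            self.within_block_assoc_prob,
            self.cross_block_assoc_prob,
            self.partner_overlap_within_block,
            self.partner_background_prob,
            self.noise_flip_prob,
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not self.within_block_assoc_prob > self.cross_block_assoc_prob:
            raise ValueError(
                "within_block_assoc_prob must exceed cross_block_assoc_prob "
                "(no signal planted otherwise)"
            )
        unknown = set(self.partner_pool_sizes) - set(LNCRNA_VIEWS + DISEASE_VIEWS)
        if unknown:
            raise ValueError(f"unknown omic views: {sorted(unknown)}")
        return self

    # Block assignment is deterministic: entity i (in lexicographic ID
    # order) belongs to block i mod n_blocks, so every block is populated.
    @property
    def lncrna_ids(self) -> list[str]:
        return [f"L{i + 1:04d}" for i in range(self.n_lncrna)]

    @property
    def disease_ids(self) -> list[str]:
        return [f"D{i + 1:04d}" for i in range(self.n_disease)]

    @property
    def block_assignment_l(self) -> dict[str, int]:
        return {lid: i % self.n_blocks for i, lid in enumerate(self.lncrna_ids)}

    @property
    def block_assignment_d(self) -> dict[str, int]:
        return {did: i % self.n_blocks for i, did in enumerate(self.disease_ids)}

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _block_vector(ids: list[str], assignment: dict[str, int]) -> np.ndarray:
    return np.array([assignment[i] for i in ids])


def _simulate_links(
    world: PlantedWorld, view: str, rng: np.random.Generator
) -> OmicLinkTable:
    side_ids = world.lncrna_ids if view in LNCRNA_VIEWS else world.disease_ids
    assignment = (
        world.block_assignment_l if view in LNCRNA_VIEWS else world.block_assignment_d
    )
    pool = world.partner_pool_sizes.get(view, 0)
    prefix = _VIEW_PREFIX[view]
    right_ids = [f"{prefix}{i + 1:04d}" for i in range(pool)]
    # partner pool split into per-block groups; same-block entities draw from
    # the same group at the overlap rate, everyone sees the background rate
    partner_block = np.arange(pool) % world.n_blocks
    entity_block = _block_vector(side_ids, assignment)
    same = entity_block[:, None] == partner_block[None, :]
    prob = np.where(same, world.partner_overlap_within_block, world.partner_background_prob)
    links = (rng.random(prob.shape) < prob).astype(np.int8)
    return OmicLinkTable(view, list(side_ids), right_ids, links)


def _simulate_ontology(world: PlantedWorld, rng: np.random.Generator) -> OntologyTable:
    """Random binary-ish tree: root -> one subtree per block -> disease leaves."""
    edges: list[tuple[str, str]] = []
    counter = 0

    def split(members: list[str], parent: str) -> None:
        nonlocal counter
        if len(members) == 1:
            edges.append((members[0], parent))
            return
        members = list(members)
        rng.shuffle(members)
        cut = int(rng.integers(1, len(members)))
        for half in (members[:cut], members[cut:]):
            if len(half) == 1:
                edges.append((half[0], parent))
            else:
                counter += 1
                node = f"N{counter:04d}"
                edges.append((node, parent))
                split(sorted(half), node)

    by_block: dict[int, list[str]] = {}
    for did, b in world.block_assignment_d.items():
        by_block.setdefault(b, []).append(did)
    for b in sorted(by_block):
        block_node = f"B{b:02d}"
        edges.append((block_node, "ROOT"))
        split(sorted(by_block[b]), block_node)
    return OntologyTable(sorted(edges))


def simulate_world(world: PlantedWorld) -> Bundle:
    """Draw a complete input bundle from a planted-world configuration.

    The association cell (i, j) is Bernoulli with the within- or cross-block
    probability according to whether lncRNA i and disease j share a block,
    then flipped with ``noise_flip_prob``. The returned bundle's ``truth``
    attribute keeps the pre-flip matrix for recovery measurements; it is not
    part of the on-disk bundle.
    """
    world.validate()
    rng = np.random.default_rng(world.seed)
    bl = _block_vector(world.lncrna_ids, world.block_assignment_l)
    bd = _block_vector(world.disease_ids, world.block_assignment_d)
    same = bl[:, None] == bd[None, :]
    prob = np.where(same, world.within_block_assoc_prob, world.cross_block_assoc_prob)
    clean = (rng.random(prob.shape) < prob).astype(np.int8)
    flip = rng.random(prob.shape) < world.noise_flip_prob
    noisy = np.where(flip, 1 - clean, clean).astype(np.int8)
    assoc = AssociationMatrix(world.lncrna_ids, world.disease_ids, noisy)
    links = {v: _simulate_links(world, v, rng) for v in LNCRNA_VIEWS + DISEASE_VIEWS}
    ontology = _simulate_ontology(world, rng)
    return Bundle(
        associations=assoc, links=links, ontology=ontology, truth=clean
    ).validate()


def write_bundle(bundle: Bundle, directory: str | Path, world: PlantedWorld | None = None) -> dict:
    """Write all bundle tables under ``directory``; return the manifest.

    Files: ``associations.tsv``, ``ontology.tsv`` and one edge list per omic
    view — n_views + 2 files plus ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}}
    io.write_associations(bundle.associations, directory / "associations.tsv")
    manifest["files"]["associations"] = "associations.tsv"
    if bundle.ontology is not None:
        io.write_ontology(bundle.ontology, directory / "ontology.tsv")
        manifest["files"]["ontology"] = "ontology.tsv"
    for view, table in sorted(bundle.links.items()):
        io.write_links(table, directory / f"{view}.tsv")
        manifest["files"][view] = f"{view}.tsv"
    if world is not None:
        manifest["seed"] = world.seed
        manifest["config"] = asdict(world)
        manifest["config_hash"] = world.config_hash()
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_bundle(directory: str | Path) -> Bundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    files = manifest["files"]
    assoc = io.read_associations(directory / files["associations"])
    ontology = (
        io.read_ontology(directory / files["ontology"]) if "ontology" in files else None
    )
    links = {
        view: io.read_links(directory / fname, view)
        for view, fname in files.items()
        if view not in ("associations", "ontology")
    }
    return Bundle(associations=assoc, links=links, ontology=ontology).validate()
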