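"""Core in-memory containers shared by every stage of the pipeline.

All matrices are dense numpy arrays ordered lexicographically by entity ID;
files carry IDs, never indices. Containers validate their own invariants at
construction time via ``validate()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

# canonical omic views and which entity side each one annotates
LNCRNA_VIEWS = ("lncrna_mrna", "lncrna_rbp", "lncrna_protein")
DISEASE_VIEWS = ("disease_metabolite", "disease_circrna")
VIEW_SIDES: Mapping[str, str] = {
    **{v: "lncrna" for v in LNCRNA_VIEWS},
    **{v: "disease" for v in DISEASE_VIEWS},
}


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} IDs")


def _check_binary(values: np.ndarray, what: str) -> None:
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{what} values must be binary 0/1")


@dataclass
class AssociationMatrix:
    """Binary lncRNA x disease association relation A.

    ``values[i, j] == 1`` records a known association between lncRNA
    ``lncrna_ids[i]`` and disease ``disease_ids[j]``. This is both the
    supervision signal and the input profile for the Gaussian interaction
    profile kernel.
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def validate(self) -> "AssociationMatrix":
        _check_unique(self.lncrna_ids, "lncRNA")
        _check_unique(self.disease_ids, "disease")
        if self.values.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError("association matrix shape does not match ID lists")
        _check_binary(self.values, "association")
        return self

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.lncrna_ids), list(self.disease_ids), self.values.copy()
        )


@dataclass
class OmicLinkTable:
    """Bipartite binary links between one entity side and an omic partner pool.

    ``view_name`` is one of the canonical views (lncrna_mrna, lncrna_rbp,
    lncrna_protein, disease_metabolite, disease_circrna); the left namespace
    is the lncRNA or disease side accordingly.
    """

    view_name: str
    left_ids: list[str]
    right_ids: list[str]
    links: np.ndarray

    def validate(self) -> "OmicLinkTable":
        if self.view_name not in VIEW_SIDES:
            raise ValueError(f"unknown omic view {self.view_name!r}")
        _check_unique(self.left_ids, "left")
        _check_unique(self.right_ids, "right")
        if self.links.shape != (len(self.left_ids), len(self.right_ids)):
            raise ValueError("link matrix shape does not match ID lists")
        _check_binary(self.links, "link")
        return self

    @property
    def side(self) -> str:
        return VIEW_SIDES[self.view_name]

    def partner_sets(self) -> dict[str, frozenset[str]]:
        """Partner set P_i per left entity, keyed by ID."""
        right = np.asarray(self.right_ids, dtype=object)
        return {
            lid: frozenset(right[self.links[i] == 1])
            for i, lid in enumerate(self.left_ids)
        }


@dataclass
class OntologyTable:
    """IS_A parent-child relation over disease terms, single-rooted and acyclic."""

    edges: list[tuple[str, str]]  # (child, parent)

    def validate(self) -> "OntologyTable":
        children = {c for c, _ in self.edges}
        nodes = children | {p for _, p in self.edges}
        roots = nodes - children
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {len(roots)}")
        # Kahn topological sort to reject cycles
        parents: dict[str, set[str]] = {n: set() for n in nodes}
        for c, p in self.edges:
            parents[c].add(p)
        order, frontier = 0, [next(iter(roots))]
        remaining = {c: set(ps) for c, ps in parents.items()}
        child_of: dict[str, set[str]] = {n: set() for n in nodes}
        for c, p in self.edges:
            child_of[p].add(c)
        while frontier:
            node = frontier.pop()
            order += 1
            for ch in child_of[node]:
                remaining[ch].discard(node)
                if not remaining[ch]:
                    frontier.append(ch)
        if order != len(nodes):
            raise ValueError("ontology contains a cycle")
        return self

    @property
    def nodes(self) -> set[str]:
        return {c for c, _ in self.edges} | {p for _, p in self.edges}

    @property
    def root(self) -> str:
        children = {c for c, _ in self.edges}
        (root,) = self.nodes - children
        return root

    def ancestors(self, node: str) -> frozenset[str]:
        """All ancestors of ``node`` on the IS_A DAG, including ``node`` itself."""
        parents: dict[str, set[str]] = {}
        for c, p in self.edges:
            parents.setdefault(c, set()).add(p)
        seen: set[str] = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(parents.get(cur, ()))
        return frozenset(seen)


@dataclass
class SimilarityMatrix:
    """Square symmetric entity-entity similarity with values in [0, 1]."""

    entity_ids: list[str]
    values: np.ndarray
    source_view: str = ""

    def validate(self, atol: float = 1e-12) -> "SimilarityMatrix":
        _check_unique(self.entity_ids, "entity")
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over entity_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity values must be finite")
        if np.abs(self.values - self.values.T).max(initial=0.0) > atol:
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min(initial=0.0) < -atol or self.values.max(initial=0.0) > 1 + atol:
            raise ValueError("similarity values must lie in [0, 1]")
        return self


@dataclass
class EmbeddingMatrix:
    """Per-entity feature vectors (entities x dim)."""

    entity_ids: list[str]
    vectors: np.ndarray
    provenance: str = "raw-rwr"  # raw-rwr | dae

    def validate(self) -> "EmbeddingMatrix":
        _check_unique(self.entity_ids, "entity")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.entity_ids):
            raise ValueError("embedding matrix must be entities x dim")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding values must be finite")
        return self

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.vectors[self.entity_ids.index(entity_id)]
        except ValueError as exc:
            raise KeyError(f"no embedding for entity {entity_id!r}") from exc


@dataclass
class Bundle:
    """A complete input bundle: associations, omic link tables, ontology.

    ``truth`` optionally carries the noise-free planted association matrix for
    synthetic worlds; it is never written as an input file and never used for
    training, only for measuring recovery of planted structure.
    """

    associations: AssociationMatrix
    links: dict[str, OmicLinkTable] = field(default_factory=dict)
    ontology: OntologyTable | None = None
    semantic_similarity: SimilarityMatrix | None = None
    truth: np.ndarray | None = None

    def validate(self) -> "Bundle":
        self.associations.validate()
        for name, table in self.links.items():
            table.validate()
            if table.view_name != name:
                raise ValueError(f"link table keyed {name!r} has view {table.view_name!r}")
            side_ids = (
                self.associations.lncrna_ids
                if table.side == "lncrna"
                else self.associations.disease_ids
            )
            if table.left_ids != side_ids:
                raise ValueError(f"view {name!r} left IDs do not match the {table.side} set")
        if self.ontology is not None:
            self.ontology.validate()
        return self
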