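"""Core data model for anatomical networks.

An anatomical network represents a skull as a simple, undirected, unweighted
graph: bones are nodes, suture joints / bone contacts are links.  Every bone
carries a laterality (``left``, ``right`` or ``midline``) and, for bilaterally
paired bones, a ``pair_id`` shared with its antimere.  The model supports
skulls with a missing pair member (a pair_id with a single bone present is
legal and excluded from mirror-symmetry comparison).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

LATERALITIES = ("left", "right", "midline")

_SUFFIX_RE = re.compile(r"(.*)_([LR])$")


class NetworkError(ValueError):
    """Raised for violations of the anatomical-network model."""


@dataclass(frozen=True)
class Bone:
    """A named skull bone.

    ``laterality`` is one of ``left``/``right``/``midline``; paired bones
    share a ``pair_id`` with their opposite-side antimere, midline bones
    have none.
    """

    name: str
    laterality: str = "midline"
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise NetworkError(
                f"bone {self.name!r}: laterality must be one of {LATERALITIES}, "
                f"got {self.laterality!r}"
            )
        if self.laterality == "midline" and self.pair_id is not None:
            raise NetworkError(f"midline bone {self.name!r} must not carry a pair_id")
        if self.laterality in ("left", "right") and self.pair_id is None:
            raise NetworkError(f"{self.laterality} bone {self.name!r} requires a pair_id")


@dataclass
class NetworkValidationReport:
    """Result of :func:`validate`: connectivity, symmetry and isolation checks."""

    is_connected: bool
    asymmetric_links: list[tuple[str, str]]
    isolated_bones: list[str]

    @property
    def is_mirror_symmetric(self) -> bool:
        return not self.asymmetric_links

    def to_dict(self) -> dict:
        return {
            "is_connected": self.is_connected,
            "asymmetric_links": [list(l) for l in self.asymmetric_links],
            "isolated_bones": list(self.isolated_bones),
        }


class AnatomicalNetwork:
    """A skull modelled as a simple undirected unweighted graph of bones.

    Parameters
    ----------
    taxon:
        Label of the taxon the skull belongs to.
    bones:
        Iterable of :class:`Bone`.  Names must be unique (case-sensitive,
        compared after whitespace trimming).
    links:
        Iterable of unordered bone-name pairs.  Self-loops and duplicates
        are rejected; every endpoint must be a declared bone.
    notes:
        Free-text provenance.
    """

    def __init__(
        self,
        taxon: str,
        bones: Iterable[Bone],
        links: Iterable[tuple[str, str]],
        notes: str = "",
    ) -> None:
        self.taxon = taxon
        self.notes = notes
        self.bones: dict[str, Bone] = {}
        for bone in bones:
            if bone.name in self.bones:
                raise NetworkError(f"duplicate bone name {bone.name!r}")
            self.bones[bone.name] = bone
        if len(self.bones) < 2:
            raise NetworkError("an anatomical network needs at least 2 bones")
        self._check_pairs()
        self.links: set[frozenset[str]] = set()
        for a, b in links:
            if a == b:
                raise NetworkError(f"self-loop at bone {a!r}")
            for end in (a, b):
                if end not in self.bones:
                    raise NetworkError(f"link ({a!r}, {b!r}) references undeclared bone {end!r}")
            key = frozenset((a, b))
            if key in self.links:
                raise NetworkError(f"duplicate link ({a!r}, {b!r})")
            self.links.add(key)

    def _check_pairs(self) -> None:
        by_pair: dict[str, list[Bone]] = {}
        for bone in self.bones.values():
            if bone.pair_id is not None:
                by_pair.setdefault(bone.pair_id, []).append(bone)
        for pid, members in by_pair.items():
            if len(members) > 2:
                raise NetworkError(f"pair_id {pid!r} shared by more than two bones")
            if len(members) == 2 and members[0].laterality == members[1].laterality:
                raise NetworkError(
                    f"pair_id {pid!r}: both bones are {members[0].laterality}; "
                    "a pair needs opposite lateralities"
                )

    # -- basic counts ------------------------------------------------------
    @property
    def n_bones(self) -> int:
        return len(self.bones)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def degree(self, name: str) -> int:
        return sum(1 for link in self.links if name in link)

    # -- pairing helpers ---------------------------------------------------
    def partner(self, name: str) -> str | None:
        """Name of the opposite-side bone of a pair, or None (midline/singleton)."""
        bone = self.bones[name]
        if bone.pair_id is None:
            return None
        for other in self.bones.values():
            if other.pair_id == bone.pair_id and other.name != name:
                return other.name
        return None

    def mirror_of(self, name: str) -> str | None:
        """Mirror image of a bone: its partner if paired, itself if midline.

        Returns None for a paired-but-singleton bone (missing antimere),
        which is excluded from symmetry comparison.
        """
        bone = self.bones[name]
        if bone.laterality == "midline":
            return name
        return self.partner(name)

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for bone in self.bones.values():
            g.add_node(bone.name, laterality=bone.laterality,
                       pair_id=bone.pair_id if bone.pair_id is not None else "")
        for link in self.links:
            a, b = sorted(link)
            g.add_edge(a, b)
        g.graph["taxon"] = self.taxon
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, taxon: str | None = None,
                      notes: str = "") -> "AnatomicalNetwork":
        bones = []
        for name, attrs in g.nodes(data=True):
            pid = attrs.get("pair_id") or None
            bones.append(Bone(str(name), attrs.get("laterality", "midline"), pid))
        links = [(str(a), str(b)) for a, b in g.edges()]
        return cls(taxon or g.graph.get("taxon", ""), bones, links, notes=notes)

    def copy(self) -> "AnatomicalNetwork":
        return AnatomicalNetwork(
            self.taxon, list(self.bones.values()),
            [tuple(sorted(l)) for l in self.links], notes=self.notes,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnatomicalNetwork):
            return NotImplemented
        return (self.taxon == other.taxon and self.bones == other.bones
                and self.links == other.links)

    def __repr__(self) -> str:
        return (f"AnatomicalNetwork(taxon={self.taxon!r}, N={self.n_bones}, "
                f"K={self.n_links})")


# ---------------------------------------------------------------------------
# bone-attribute inference


def _bone_from_name(name: str, attributes: Mapping[str, tuple[str, str | None]] | None) -> Bone:
    if attributes and name in attributes:
        laterality, pair_id = attributes[name]
        return Bone(name, laterality, pair_id)
    m = _SUFFIX_RE.match(name)
    if m:
        side = "left" if m.group(2) == "L" else "right"
        return Bone(name, side, pair_id=m.group(1))
    return Bone(name)


def read_attribute_table(path: str | Path) -> dict[str, tuple[str, str | None]]:
    """Read a ``name,laterality,pair_id`` CSV into an attribute mapping."""
    attrs: dict[str, tuple[str, str | None]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if i == 1 and parts[0].lower() == "name":
                continue
            if len(parts) < 2:
                raise NetworkError(f"{path}: malformed attribute row at line {i}: {line!r}")
            name, lat = parts[0], parts[1].lower()
            pid = parts[2] if len(parts) > 2 and parts[2] else None
            attrs[name] = (lat, pid)
    return attrs


# ---------------------------------------------------------------------------
# edge-list I/O

_HEADER_TOKENS = {("bone_1", "bone_2"), ("bone1", "bone2"),
                  ("source", "target"), ("from", "to")}


def load_edge_list(
    path: str | Path,
    attributes: Mapping[str, tuple[str, str | None]] | str | Path | None = None,
    taxon: str | None = None,
) -> AnatomicalNetwork:
    """Load an anatomical network from a two-column delimited edge list.

    Rows are ``bone_1,bone_2`` (comma or tab separated); an optional header
    and ``#`` comment lines are skipped.  Bone attributes come from
    ``attributes`` (mapping or CSV path); names without attributes default to
    midline, except names with an ``_L``/``_R`` suffix which are parsed as a
    left/right pair.
    """
    path = Path(path)
    if isinstance(attributes, (str, Path)):
        attributes = read_attribute_table(attributes)
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    with open(path, encoding="utf-8") as fh:
        first_data_row = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise NetworkError(f"{path}: malformed row at line {lineno}: {line!r}")
            a, b = parts
            if first_data_row:
                first_data_row = False
                if (a.lower(), b.lower()) in _HEADER_TOKENS:
                    continue
            if a == b:
                raise NetworkError(f"{path}: self-loop at line {lineno}")
            key = frozenset((a, b))
            if key in seen:
                raise NetworkError(f"{path}: duplicate link at line {lineno}: {a},{b}")
            seen.add(key)
            edges.append((a, b))
    names = sorted({n for e in edges for n in e})
    bones = [_bone_from_name(n, attributes) for n in names]
    return AnatomicalNetwork(taxon or path.stem, bones, edges)


def write_edge_list(net: AnatomicalNetwork, path: str | Path) -> None:
    """Write the link set as a ``bone_1,bone_2`` CSV (sorted, deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bone_1,bone_2\n")
        for a, b in sorted(tuple(sorted(l)) for l in net.links):
            fh.write(f"{a},{b}\n")


# ---------------------------------------------------------------------------
# GEXF / GraphML I/O (Gephi interoperability)


def _check_simple_unweighted(g: nx.Graph, path: str | Path) -> None:
    if g.is_directed() or g.is_multigraph():
        raise NetworkError(
            f"{path}: anatomical networks are simple, undirected, unweighted")
    for a, b, attrs in g.edges(data=True):
        w = attrs.get("weight", 1)
        if float(w) != 1.0:
            raise NetworkError(
                f"{path}: anatomical networks are simple, undirected, unweighted "
                f"(edge ({a}, {b}) has weight {w})")


def load_gexf(path: str | Path, taxon: str | None = None) -> AnatomicalNetwork:
    """Load a network from GEXF (or GraphML, by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
    else:
        g = nx.read_gexf(path)
    _check_simple_unweighted(g, path)
    g = nx.relabel_nodes(g, {n: g.nodes[n].get("label", n) for n in g.nodes})
    return AnatomicalNetwork.from_networkx(g, taxon=taxon or path.stem)


def write_gexf(net: AnatomicalNetwork, path: str | Path) -> None:
    """Write the network as GEXF 1.2 (or GraphML, by extension); undirected."""
    path = Path(path)
    g = net.to_networkx()
    if path.suffix.lower() == ".graphml":
        nx.write_graphml(g, path)
    else:
        nx.write_gexf(g, path, version="1.2draft")


# ---------------------------------------------------------------------------
# validation


def validate(net: AnatomicalNetwork) -> NetworkValidationReport:
    """Check connectivity, mirror symmetry over pairs, and isolated bones.

    A link ``(x, y)`` is asymmetric when its mirror image — mapping each
    paired bone to its antimere and each midline bone to itself — is absent
    from the link set.  Links touching a paired-but-singleton bone (missing
    antimere) are excluded from the comparison.  The input is not mutated.
    """
    g = net.to_networkx()
    is_connected = nx.is_connected(g) if g.number_of_nodes() else False
    isolated = sorted(n for n in g.nodes if g.degree(n) == 0)
    asymmetric: list[tuple[str, str]] = []
    for link in net.links:
        a, b = sorted(link)
        ma, mb = net.mirror_of(a), net.mirror_of(b)
        if ma is None or mb is None:
            continue  # singleton pair member: no mirror to compare against
        if frozenset((ma, mb)) == link:
            continue  # self-mirrored (midline-midline or within-pair) link
        if frozenset((ma, mb)) not in net.links:
            asymmetric.append((a, b))
    return NetworkValidationReport(
        is_connected=is_connected,
        asymmetric_links=sorted(asymmetric),
        isolated_bones=isolated,
    )
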