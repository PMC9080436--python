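"""Synthetic skull-network and trait generators.

Real bone-contact codings are rarely redistributable, so this module
generates skull-like anatomical networks with the structural features the
analysis pipeline consumes: ~35 bones of which ~20% are midline (unpaired),
link counts in the high tens to low hundreds, guaranteed connectivity, and
exact mirror symmetry of the left/right link sets (optionally broken by a
configurable asymmetry fraction).  Two "telescoping" editing modes emulate
the cetacean patterns: a prograde mode concentrates new contacts on a
midline occipital anchor (raising degree heterogeneity), a retrograde mode
adds mirrored contact pairs to a paired rostral anchor (raising density).

The generator aims at counts, symmetry and connectivity — not at the true
suture anatomy of any taxon; the default 35-bone vocabulary (7 midline + 14
pairs) is a documented stand-in naming scheme.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_model import AnatomicalNetwork, Bone, NetworkError

MIDLINE_BONES = [
    "Vomer", "Supraoccipital", "Basioccipital", "Basisphenoid",
    "Presphenoid", "Ethmoid", "Mesethmoid",
]
PAIRED_BONES = [
    "Nasal", "Premaxilla", "Maxilla", "Frontal", "Parietal", "Squamosal",
    "Jugal", "Lacrimal", "Palatine", "Pterygoid", "Alisphenoid",
    "Orbitosphenoid", "Exoccipital", "Tympanic",
]
# attachment propensity: midline bones attract contacts preferentially,
# strongest for the vomer/supraoccipital analogues
_PROPENSITY = {"Vomer": 4.0, "Supraoccipital": 4.0}
_MIDLINE_PROPENSITY = 2.0
_PAIRED_PROPENSITY = 1.0
_HUB_DEGREE_FLOOR = 6

TELESCOPING_MODES = ("none", "prograde", "retrograde")


@dataclass
class SkullGenConfig:
    """Configuration of the skull-network generator."""

    n_unpaired: int = 7
    n_pairs: int = 14
    target_links: int = 90
    asymmetry: float = 0.0
    telescoping_mode: str = "none"
    extra_links: int = 0
    seed: int = 0

    @property
    def n_bones(self) -> int:
        return self.n_unpaired + 2 * self.n_pairs

    def check(self) -> None:
        n = self.n_bones
        if self.n_unpaired < 0 or self.n_pairs < 0 or n < 2:
            raise NetworkError("need at least 2 bones")
        if self.n_unpaired == 0 and self.n_pairs == 0:
            raise NetworkError("empty skull")
        if not (n - 1 <= self.target_links <= n * (n - 1) // 2):
            raise NetworkError(
                f"target_links={self.target_links} infeasible for N={n} "
                f"(must lie in [{n - 1}, {n * (n - 1) // 2}])")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise NetworkError("asymmetry must lie in [0, 1]")
        if self.telescoping_mode not in TELESCOPING_MODES:
            raise NetworkError(f"unknown telescoping mode {self.telescoping_mode!r}")
        if self.extra_links < 0:
            raise NetworkError("extra_links must be >= 0")


def _bone_names(config: SkullGenConfig) -> tuple[list[str], list[str]]:
    """Midline names and pair stems; the documented vocabulary when it fits."""
    if config.n_unpaired <= len(MIDLINE_BONES):
        mids = MIDLINE_BONES[: config.n_unpaired]
    else:
        mids = MIDLINE_BONES + [f"Midline{i}" for i in
                                range(len(MIDLINE_BONES) + 1, config.n_unpaired + 1)]
    if config.n_pairs <= len(PAIRED_BONES):
        pairs = PAIRED_BONES[: config.n_pairs]
    else:
        pairs = PAIRED_BONES + [f"Pair{i}" for i in
                                range(len(PAIRED_BONES) + 1, config.n_pairs + 1)]
    return mids, pairs


def _propensity(name: str) -> float:
    if name in _PROPENSITY:
        return _PROPENSITY[name]
    if name in MIDLINE_BONES or name.startswith("Midline"):
        return _MIDLINE_PROPENSITY
    return _PAIRED_PROPENSITY


# ---------------------------------------------------------------------------
# link orbits: the unit of sampling is a mirror-symmetry orbit of links, so
# the generated edge set is exactly mirror-symmetric by construction.

Orbit = tuple[tuple[str, str], ...]


def _all_orbits(mids: list[str], pairs: list[str]) -> list[Orbit]:
    orbits: list[Orbit] = []
    for i, a in enumerate(mids):
        for b in mids[i + 1:]:
            orbits.append(((a, b),))
    for p in pairs:
        orbits.append(((f"{p}_L", f"{p}_R"),))
        for m in mids:
            orbits.append(((m, f"{p}_L"), (m, f"{p}_R")))
    for i, p in enumerate(pairs):
        for q in pairs[i + 1:]:
            orbits.append(((f"{p}_L", f"{q}_L"), (f"{p}_R", f"{q}_R")))
            orbits.append(((f"{p}_L", f"{q}_R"), (f"{p}_R", f"{q}_L")))
    return orbits


def _orbit_weight(orbit: Orbit) -> float:
    stems = {name.rsplit("_", 1)[0] if name.endswith(("_L", "_R")) else name
             for link in orbit for name in link}
    return sum(_propensity(s) for s in stems)


def generate_skull_network(config: SkullGenConfig,
                           taxon: str = "synthetic") -> AnatomicalNetwork:
    """Generate a connected skull-like network per ``config``.

    A spanning backbone (midline chain plus one mirrored attachment per
    bone pair) guarantees connectivity; remaining links are added orbit by
    orbit under propensity-weighted sampling until exactly ``target_links``
    links exist.  With ``asymmetry`` > 0 that fraction of mirrored orbits is
    broken by deleting one side (connectivity preserved), so K drops below
    the target by the number of broken links.  Fully reproducible from
    ``config.seed``.
    """
    config.check()
    rng = np.random.default_rng(config.seed)
    mids, pairs = _bone_names(config)
    bones = [Bone(m) for m in mids]
    for p in pairs:
        bones.append(Bone(f"{p}_L", "left", pair_id=p))
        bones.append(Bone(f"{p}_R", "right", pair_id=p))

    links: set[frozenset[str]] = set()
    used: set[Orbit] = set()

    def add_orbit(orbit: Orbit) -> None:
        used.add(orbit)
        for a, b in orbit:
            links.add(frozenset((a, b)))

    # spanning backbone
    if mids:
        for a, b in zip(mids, mids[1:]):
            add_orbit(((a, b),))
        for p in pairs:
            m = mids[rng.integers(len(mids))]
            add_orbit(((m, f"{p}_L"), (m, f"{p}_R")))
    else:
        add_orbit(((f"{pairs[0]}_L", f"{pairs[0]}_R"),))
        for p, q in zip(pairs, pairs[1:]):
            add_orbit(((f"{p}_L", f"{q}_L"), (f"{p}_R", f"{q}_R")))

    # hub floor: the vomer/supraoccipital analogues are major contact hubs in
    # real skulls (roughly 5-15 contacts); guarantee them a minimum degree
    # before the random fill so telescoping edits act on a realistic base
    def degree(name: str) -> int:
        return sum(1 for l in links if name in l)

    all_orbits = _all_orbits(mids, pairs)
    for hub in [m for m in mids if m in _PROPENSITY]:
        incident = [o for o in all_orbits if o not in used
                    and any(hub in link for link in o)]
        order = rng.permutation(len(incident))
        for idx in order:
            budget = config.target_links - len(links)
            if degree(hub) >= _HUB_DEGREE_FLOOR or budget <= 0:
                break
            orbit = incident[idx]
            if len(orbit) <= budget:
                add_orbit(orbit)

    candidates = [o for o in all_orbits if o not in used]
    weights = np.array([_orbit_weight(o) for o in candidates])
    while len(links) < config.target_links:
        remaining = config.target_links - len(links)
        legal = [i for i, o in enumerate(candidates) if sum(1 for _ in o) <= remaining]
        if not legal:
            raise NetworkError("cannot reach target_links exactly: "
                               "no single-link orbit left for the last slot")
        w = weights[legal]
        pick = legal[rng.choice(len(legal), p=w / w.sum())]
        add_orbit(candidates[pick])
        del candidates[pick]
        weights = np.delete(weights, pick)

    if config.asymmetry > 0:
        links = _break_symmetry(links, used, config.asymmetry, rng)

    net = AnatomicalNetwork(taxon, bones, [tuple(sorted(l)) for l in links],
                            notes=f"generated: seed={config.seed}")
    if config.telescoping_mode != "none" and config.extra_links:
        net = apply_telescoping(net, config.telescoping_mode, config.extra_links,
                                seed=config.seed + 1)
    return net


def _break_symmetry(links: set[frozenset[str]], used: set[Orbit],
                    fraction: float, rng: np.random.Generator,
                    ) -> set[frozenset[str]]:
    import networkx as nx

    mirrored = sorted(o for o in used if len(o) == 2)
    n_break = int(round(fraction * len(mirrored)))
    order = rng.permutation(len(mirrored))
    broken = 0
    out = set(links)
    for idx in order:
        if broken >= n_break:
            break
        orbit = mirrored[idx]
        side = orbit[int(rng.integers(2))]
        candidate = out - {frozenset(side)}
        g = nx.Graph(tuple(sorted(l)) for l in candidate)
        nodes = {n for l in out for n in l}
        if len(g) == len(nodes) and nx.is_connected(g):
            out = candidate
            broken += 1
    return out


# ---------------------------------------------------------------------------
# telescoping edits


def apply_telescoping(net: AnatomicalNetwork, mode: str, extra_links: int,
                      seed: int = 0, anchor: str | None = None,
                      ) -> AnatomicalNetwork:
    """Add telescoping-style contacts around an anchor bone.

    ``prograde`` adds ``extra_links`` new links incident to a midline anchor
    (default ``Supraoccipital``), mirrored over pairs so symmetry is
    preserved; its degree — and with it the network heterogeneity — rises.
    ``retrograde`` adds ``extra_links``/2 mirrored link pairs incident to a
    left/right anchor pair (default pair_id ``Maxilla``), raising K and D
    symmetrically.  ``extra_links=0`` returns an unchanged copy.
    """
    if mode not in ("prograde", "retrograde"):
        raise NetworkError(f"unknown telescoping mode {mode!r}")
    out = net.copy()
    if extra_links == 0:
        return out
    rng = np.random.default_rng(seed)
    if mode == "prograde":
        _prograde(out, extra_links, rng, anchor or "Supraoccipital")
    else:
        _retrograde(out, extra_links, rng, anchor or "Maxilla")
    return out


def _neighbors(net: AnatomicalNetwork, name: str) -> set[str]:
    return {n for link in net.links if name in link for n in link} - {name}


def _prograde(net: AnatomicalNetwork, extra: int, rng: np.random.Generator,
              anchor: str) -> None:
    """Connect the midline anchor to the best-connected free bones.

    Prograde telescoping brings the occipital anchor into contact with the
    richly-connected rostral elements, so targets are chosen greedily by
    current degree (deterministic; mirrored over pairs to keep symmetry,
    with any odd remainder spent on a midline bone first).
    """
    if anchor not in net.bones or net.bones[anchor].laterality != "midline":
        raise NetworkError(f"prograde telescoping needs midline anchor {anchor!r}")

    def mid_free() -> list[str]:
        nb = _neighbors(net, anchor)
        free = [n for n, b in net.bones.items()
                if b.laterality == "midline" and n != anchor and n not in nb]
        return sorted(free, key=lambda m: (-net.degree(m), m))

    def pair_free() -> list[str]:
        nb = _neighbors(net, anchor)
        pids = {b.pair_id for n, b in net.bones.items()
                if b.laterality == "left" and n not in nb
                and net.partner(n) is not None and net.partner(n) not in nb}
        return sorted(pids, key=lambda p: (-_pair_degree(net, p), p))

    def _link_mid(target: str) -> None:
        net.links.add(frozenset((anchor, target)))

    if extra % 2:
        mids = mid_free()
        if not mids:
            raise NetworkError(f"anchor {anchor!r} saturated: no legal new link")
        _link_mid(mids[0])
        extra -= 1
    while extra > 0:
        pairs, mids = pair_free(), mid_free()
        best_pair = _pair_degree(net, pairs[0]) if pairs else -1
        best_mids = (net.degree(mids[0]) + net.degree(mids[1])) / 2 \
            if len(mids) >= 2 else -1
        if best_pair < 0 and best_mids < 0:
            raise NetworkError(f"anchor {anchor!r} saturated: no legal new link")
        if best_pair >= best_mids:
            left = next(n for n, b in net.bones.items()
                        if b.pair_id == pairs[0] and b.laterality == "left")
            net.links.add(frozenset((anchor, left)))
            net.links.add(frozenset((anchor, net.partner(left))))
        else:
            _link_mid(mids[0])
            _link_mid(mids[1])
        extra -= 2


def _pair_degree(net: AnatomicalNetwork, pair_id: str) -> int:
    member = next(n for n, b in net.bones.items() if b.pair_id == pair_id)
    return net.degree(member)


def _retrograde(net: AnatomicalNetwork, extra: int, rng: np.random.Generator,
                anchor_pair: str) -> None:
    members = [n for n, b in net.bones.items() if b.pair_id == anchor_pair]
    if len(members) != 2:
        raise NetworkError(
            f"retrograde telescoping needs a complete left/right pair {anchor_pair!r}")
    if extra % 2:
        raise NetworkError("retrograde telescoping adds mirrored pairs: "
                           "extra_links must be even")
    left = next(n for n in members if net.bones[n].laterality == "left")
    right = next(n for n in members if net.bones[n].laterality == "right")
    for _ in range(extra // 2):
        nb_l, nb_r = _neighbors(net, left), _neighbors(net, right)
        cands: list[tuple[frozenset[str], frozenset[str]]] = []
        for name, bone in sorted(net.bones.items()):
            if name in (left, right):
                continue
            if bone.laterality == "midline":
                if name not in nb_l and name not in nb_r:
                    cands.append((frozenset((left, name)), frozenset((right, name))))
            elif bone.laterality == "left":
                partner = net.partner(name)
                if partner is None:
                    continue
                # same-side mirrored pair
                if name not in nb_l and partner not in nb_r:
                    cands.append((frozenset((left, name)), frozenset((right, partner))))
                # cross-side mirrored pair
                if partner not in nb_l and name not in nb_r:
                    cands.append((frozenset((left, partner)), frozenset((right, name))))
        cands = [c for c in cands if c[0] not in net.links and c[1] not in net.links
                 and c[0] != c[1]]
        if not cands:
            raise NetworkError(f"anchor pair {anchor_pair!r} saturated: no legal new link")
        l1, l2 = cands[int(rng.integers(len(cands)))]
        net.links.add(l1)
        net.links.add(l2)


# ---------------------------------------------------------------------------
# trait evolution on a tree (test harness for parsimony mapping)


def evolve_character_on_tree(tree, root_value: float, step_sd: float, seed: int = 0,
                             ) -> tuple[dict[str, float], dict[int, float]]:
    """Brownian walk along the topology with unit branch lengths.

    Each node's value is its parent's value plus Normal(0, step_sd).  Returns
    the leaf values and the hidden internal-node truth (by node_id) for
    recovery scoring.
    """
    rng = np.random.default_rng(seed)
    tips: dict[str, float] = {}
    internal: dict[int, float] = {}

    def walk(node, value: float) -> None:
        if node.is_leaf:
            tips[node.label] = value
        else:
            internal[node.node_id] = value
        for child in node.children:
            walk(child, value + rng.normal(0.0, step_sd))

    walk(tree.root, root_value)
    return tips, internal


# ---------------------------------------------------------------------------
# packaged fixtures

_TABLE1_CSV = """\
taxon,group,category,N,K,D,L,C,H,P,UBR
Pakicetus,Stem Cetacea,Extinct,35,99,0.166,2.334,0.391,0.404,0.731,0.2
Protocetidae,Stem Cetacea,Extinct,35,102,0.171,2.366,0.540,0.435,0.744,0.2
Dorudon,Stem Cetacea,Extinct,35,92,0.155,2.361,0.439,0.542,0.741,0.2
Aetiocetus,Mysticeti,Extinct,35,78,0.131,2.533,0.487,0.563,0.793,0.2
Yamatocetus,Mysticeti,Extinct,35,82,0.138,2.432,0.415,0.589,0.748,0.17
Piscobalaena,Mysticeti,Extinct,35,85,0.143,2.450,0.478,0.533,0.738,0.17
Caperea,Mysticeti,Extant,35,87,0.146,2.378,0.465,0.568,0.795,0.2
Eubalaena,Mysticeti,Extant,35,95,0.160,2.333,0.489,0.581,0.795,0.2
Balaenoptera acutorostrata,Mysticeti,Extant,35,89,0.150,2.407,0.511,0.531,0.738,0.2
Balaenoptera borealis,Mysticeti,Extant,35,87,0.150,2.434,0.509,0.514,0.738,0.2
Balaenoptera edeni,Mysticeti,Extant,35,89,0.150,2.407,0.511,0.531,0.738,0.2
Balaenoptera brydei,Mysticeti,Extant,35,89,0.150,2.407,0.511,0.531,0.738,0.2
Balaenoptera musculus,Mysticeti,Extant,35,91,0.153,2.324,0.512,0.565,0.797,0.2
Balaenoptera omurai,Mysticeti,Extant,35,85,0.143,2.450,0.510,0.549,0.743,0.2
Balaenoptera physalus,Mysticeti,Extant,35,87,0.146,2.440,0.520,0.530,0.784,0.2
Balaenoptera ricei,Mysticeti,Extant,35,83,0.139,2.489,0.487,0.529,0.797,0.2
Albertocetus,Odontoceti,Extinct,35,88,0.148,2.536,0.476,0.476,0.761,0.2
Waipatia,Odontoceti,Extinct,35,97,0.163,2.457,0.392,0.557,0.669,0.2
Notocetus,Odontoceti,Extinct,35,105,0.176,2.363,0.450,0.446,0.730,0.2
Tursiops,Odontoceti,Extant,35,93,0.156,2.506,0.400,0.57,0.793,0.2
Physeter,Odontoceti,Extant,34,103,0.184,2.228,0.491,0.525,0.666,0.2
"""


def fixture_table1() -> pd.DataFrame:
    """Published per-taxon descriptor table for 21 cetacean skull networks.

    Columns: taxon, group (Stem Cetacea / Mysticeti / Odontoceti), category
    (Extant/Extinct), and the eight descriptors N, K, D, L, C, H, P, UBR.
    """
    return pd.read_csv(io.StringIO(_TABLE1_CSV))


# A composite, editable 21-taxon topology assembled from published cetacean
# phylogenies; a working fixture for the parsimony machinery, not data
# extracted from any figure.
_BALAENOPTERA = (
    "('Balaenoptera acutorostrata',('Balaenoptera borealis',"
    "(('Balaenoptera edeni','Balaenoptera brydei'),"
    "('Balaenoptera omurai',('Balaenoptera ricei',"
    "('Balaenoptera musculus','Balaenoptera physalus'))))))"
)
_MYSTICETI = ("(Aetiocetus,(Yamatocetus,(Eubalaena,(Caperea,(Piscobalaena,"
              + _BALAENOPTERA + ")))))")
_ODONTOCETI = "(Albertocetus,((Waipatia,Notocetus),(Physeter,Tursiops)))"
COMPOSITE_CETACEAN_NEWICK = (
    "(Pakicetus,(Protocetidae,(Dorudon,(" + _MYSTICETI + "," + _ODONTOCETI + "))));"
)


def composite_cetacean_tree():
    """Parse the packaged composite cetacean topology."""
    from .phylo_mapping import parse_newick

    return parse_newick(COMPOSITE_CETACEAN_NEWICK)
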