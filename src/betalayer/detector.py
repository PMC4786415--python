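"""Two-step β-layer detection in protein structures.

A β-layer is a triangular plane of three short β-strands — one per chain
of a trimer, or pseudo-threefold within one chain — crossing the bundle
axis of a coiled coil, joined by backbone hydrogen bonds between the
central residues of the strands.  The search runs in two steps:

1. **Torsion windows.**  Each chain's α/β torsion classes are scanned with
   seven-residue sliding windows of βββαααα and ααααβββ; every matching
   window nominates its βββ triplet as a candidate strand (a triplet hit
   by both windows is one candidate recording both patterns).
2. **Cross-strand hydrogen bonds.**  Candidate strands are linked when
   their central (β₂) residues share a backbone N-O contact within 3.5 Å
   inside the (possibly assembly-expanded) model; connected components of
   two or more strands are reported as β-layers, with three strands being
   the canonical case.

Detected layers are annotated with the capping class of their interaction
network (a lysine in β₁ marks a C-cap of the upstream helices, a
hydrophobic β₁ an N-cap of the downstream ones) and with the type of
secondary-structure transition they mediate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import BackboneChain, StructureModel
from .geometry import HBOND_CUTOFF, HBondContact, TorsionSeries, backbone_hbonds, compute_torsions

#: Hydrophobic residues that mark an N-capping β-layer when found in β₁.
NCAP_HYDROPHOBIC = set("AVLIMF")

WINDOW_PATTERNS = ("bbbaaaa", "aaaabbb")


@dataclass
class StrandCandidate:
    """A three-residue β triplet flanked by at least four α on one side."""

    chain_id: str
    indices: tuple[int, int, int]       # 0-based positions in the chain
    seq_ids: tuple[int, int, int]       # author numbering
    sequence: str
    patterns: frozenset[str]            # subset of {"bbbaaaa", "aaaabbb"}

    @property
    def central_index(self) -> int:
        return self.indices[1]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.indices[0])


@dataclass
class BetaLayer:
    """A connected set of candidate strands hydrogen-bonded at their centers."""

    strands: list[StrandCandidate]
    hbonds: list[HBondContact]
    capping: str = "unclassified"
    transition_type: str = "other"
    register_string: str = ""

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def canonical(self) -> bool:
        return self.n_strands == 3

    @property
    def chain_ids(self) -> list[str]:
        return [s.chain_id for s in self.strands]

    @property
    def sequence(self) -> str:
        return self.strands[0].sequence


def scan_windows(
    torsions: dict[str, TorsionSeries],
    chains: dict[str, BackboneChain],
) -> list[StrandCandidate]:
    """Candidate strands from seven-residue βββαααα / ααααβββ windows.

    Windows never span undefined classes (chain breaks, incomplete
    residues), so strands at chain termini with fewer than four flanking
    residues on either side are not matched.
    """
    candidates: dict[tuple[str, int], StrandCandidate] = {}
    for chain_id, ts in torsions.items():
        chain = chains[chain_id]
        s = ts.class_string
        for start in range(len(s) - 6):
            window = s[start : start + 7]
            for pattern in WINDOW_PATTERNS:
                if window != pattern:
                    continue
                offset = 0 if pattern == "bbbaaaa" else 4
                idx = (start + offset, start + offset + 1, start + offset + 2)
                key = (chain_id, idx[0])
                if key in candidates:
                    old = candidates[key]
                    candidates[key] = StrandCandidate(
                        chain_id, idx, old.seq_ids, old.sequence,
                        old.patterns | {pattern},
                    )
                else:
                    candidates[key] = StrandCandidate(
                        chain_id,
                        idx,
                        tuple(chain.seq_ids[i] for i in idx),
                        "".join(chain.aas[i] for i in idx),
                        frozenset({pattern}),
                    )
    return sorted(candidates.values(), key=lambda c: c.key)


def pair_strands(
    candidates: list[StrandCandidate],
    model: StructureModel,
    cutoff: float = HBOND_CUTOFF,
) -> list[BetaLayer]:
    """Group candidate strands into β-layers by central-residue H-bonds.

    An edge joins two candidates whose central (β₂) residues share a
    backbone N-O contact within the cutoff; connected components of at
    least two strands become layers.  Strands of the same chain may pair
    (monomers with pseudo-threefold symmetry).
    """
    chains = {c.chain_id: c for c in model.chains}
    n = len(candidates)
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    edge_contacts: dict[tuple[int, int], list[HBondContact]] = {}
    for i, j in itertools.combinations(range(n), 2):
        ci, cj = candidates[i], candidates[j]
        contacts = backbone_hbonds(
            (chains[ci.chain_id], ci.central_index),
            (chains[cj.chain_id], cj.central_index),
            cutoff=cutoff,
        )
        if contacts:
            adjacency[i].add(j)
            adjacency[j].add(i)
            edge_contacts[(i, j)] = contacts
    layers = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        component = {i}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in adjacency[u]:
                if v not in component:
                    component.add(v)
                    stack.append(v)
        seen |= component
        if len(component) < 2:
            continue
        members = sorted(component)
        strands = sorted((candidates[k] for k in members), key=lambda c: c.key)
        hbonds = [
            c
            for a, b in itertools.combinations(members, 2)
            for c in edge_contacts.get((a, b), [])
        ]
        layers.append(BetaLayer(strands=strands, hbonds=hbonds))
    layers.sort(key=lambda l: (l.strands[0].chain_id, l.strands[0].seq_ids[0]))
    return layers


def classify_capping(layer: BetaLayer) -> str:
    """Capping class from the β₁ residue of each strand.

    Lysine in β₁ anchors a C-cap of the upstream helices; a hydrophobic
    β₁ an N-cap of the downstream ones.  Strands that disagree yield
    "mixed"; anything else is "unclassified".
    """

    def one(strand: StrandCandidate) -> str:
        b1 = strand.sequence[0]
        if b1 == "K":
            return "C-cap"
        if b1 in NCAP_HYDROPHOBIC:
            return "N-cap"
        return "unclassified"

    labels = {one(s) for s in layer.strands}
    if len(labels) == 1:
        return labels.pop()
    labels.discard("unclassified")
    if len(labels) == 1:
        return labels.pop()
    return "mixed"


def annotate_transition(
    layer: BetaLayer, torsions: dict[str, TorsionSeries]
) -> str:
    """Transition type from the secondary structure flanking the layer."""

    def one(strand: StrandCandidate) -> str:
        ts = torsions[strand.chain_id]
        b1, _, b3 = strand.indices
        up = [ts.ss_class[i] for i in range(max(0, b1 - 4), b1)]
        down = [ts.ss_class[i] for i in range(b3 + 1, min(len(ts), b3 + 5))]
        up_alpha = len(up) == 4 and all(c == "alpha" for c in up)
        down_alpha = len(down) == 4 and all(c == "alpha" for c in down)
        up_beta = bool(up) and up[-1] == "beta"
        down_beta = bool(down) and down[0] == "beta"
        if up_alpha and down_alpha:
            return "cc-to-cc"
        if up_alpha and down_beta:
            return "cc-to-β"
        if up_beta and down_alpha:
            return "β-to-cc"
        if b1 < 4:
            return "Nterm-to-cc"
        if up_alpha and len(down) < 4:
            return "cc-to-coil"
        return "other"

    labels = {one(s) for s in layer.strands}
    return labels.pop() if len(labels) == 1 else "other"


def detect_beta_layers(
    model: StructureModel,
    cutoff: float = HBOND_CUTOFF,
    strict_trimer: bool = False,
) -> list[BetaLayer]:
    """Full two-step β-layer detection on a structure model.

    Composes torsion computation, window scanning and central-residue
    pairing; layers are returned sorted by (chain id, first residue) and
    annotated with capping and transition type.  ``strict_trimer``
    restricts the report to canonical three-strand layers.
    """
    torsions = {c.chain_id: compute_torsions(c) for c in model.chains}
    chains = {c.chain_id: c for c in model.chains}
    candidates = scan_windows(torsions, chains)
    layers = pair_strands(candidates, model, cutoff=cutoff)
    if strict_trimer:
        layers = [l for l in layers if l.canonical]
    for layer in layers:
        layer.capping = classify_capping(layer)
        layer.transition_type = annotate_transition(layer, torsions)
    return layers


def annotate_layer_registers(model: StructureModel, layers: list[BetaLayer]) -> None:
    """Fill each layer's register string from the bundle geometry.

    Needs at least two chains to define a bundle axis; layers whose
    register cannot be assigned keep an empty string.  The string spans
    the first strand's residues plus three flanking residues each side,
    e.g. ``a-b-c-β1-β2-β3-e-f-g``.
    """
    from .supercoil import assign_register, bundle_axis

    if len(model.chains) < 2 or not layers:
        return
    try:
        axis = bundle_axis(model.chains)
    except ValueError:
        return
    windows: dict[str, list[tuple[int, int, int]]] = {}
    for layer in layers:
        for s in layer.strands:
            windows.setdefault(s.chain_id, []).append(s.indices)
    labels = {
        cid: assign_register(model.chain(cid), axis, wins)
        for cid, wins in windows.items()
    }
    for layer in layers:
        s = layer.strands[0]
        lab = labels[s.chain_id]
        b1, _, b3 = s.indices
        lo, hi = max(0, b1 - 3), min(len(lab), b3 + 4)
        layer.register_string = "-".join(lab[lo:hi])


def layers_to_table(layers: list[BetaLayer]) -> pd.DataFrame:
    """Report table: one row per detected layer (TSV/JSON-ready)."""
    rows = []
    for k, layer in enumerate(layers, start=1):
        first = layer.strands[0]
        rows.append(
            {
                "layer_id": k,
                "chains": ",".join(layer.chain_ids),
                "strand_residues": ";".join(
                    f"{s.chain_id}:{s.seq_ids[0]}-{s.seq_ids[2]}" for s in layer.strands
                ),
                "sequence": first.sequence,
                "n_strands": layer.n_strands,
                "canonical": layer.canonical,
                "capping": layer.capping,
                "transition_type": layer.transition_type,
                "register": layer.register_string,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "layer_id", "chains", "strand_residues", "sequence", "n_strands",
            "canonical", "capping", "transition_type", "register",
        ],
    )
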