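"""Backbone dihedrals, Ramachandran-region classification and hydrogen bonds.

Residues are classified into two rectangular (φ, ψ) regions that drive the
β-layer search: the α region (-70° ≤ ψ ≤ -10°, -180° ≤ φ ≤ -40°) and the
β region (20° ≤ ψ ≤ 180°, -180° ≤ φ ≤ -40°).  Box boundaries are
inclusive; the two boxes are disjoint in ψ, so no residue is both.

Backbone hydrogen bonds are tested purely by the amide-N to carbonyl-O
heavy-atom distance with an inclusive 3.5 Å cutoff; no angular term is
applied and both donor/acceptor directions qualify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .chain import BackboneChain

#: Inclusive backbone N-O distance cutoff for a hydrogen bond, in Å.
HBOND_CUTOFF = 3.5

SSClass = Literal["alpha", "beta", "other", "undefined"]


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points in degrees, in (-180, 180].

    Uses the IUPAC sign convention: looking from ``p2`` to ``p3``, a
    clockwise rotation of the far bond relative to the near bond is
    positive.  Degenerate geometry (coincident points, collinear central
    bond) yields NaN rather than raising.
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    denom = np.linalg.norm(n1) * np.linalg.norm(n2)
    if norm_b2 < 1e-9 or denom < 1e-9:
        return float("nan")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def classify_phi_psi(phi: float, psi: float) -> SSClass:
    """α/β/other class of a (φ, ψ) pair; NaN angles give ``undefined``."""
    if not (np.isfinite(phi) and np.isfinite(psi)):
        return "undefined"
    if -180.0 <= phi <= -40.0:
        if -70.0 <= psi <= -10.0:
            return "alpha"
        if 20.0 <= psi <= 180.0:
            return "beta"
    return "other"


@dataclass
class TorsionSeries:
    """Per-residue (φ, ψ) in degrees and the derived α/β class.

    NaN marks undefined angles (segment termini, incomplete residues and
    their neighbours across a chain break).
    """

    chain_id: str
    phi: np.ndarray
    psi: np.ndarray
    ss_class: list[SSClass]

    def __len__(self) -> int:
        return len(self.ss_class)

    @property
    def class_string(self) -> str:
        """One character per residue: a (alpha), b (beta), o, u."""
        return "".join(c[0] if c != "undefined" else "u" for c in self.ss_class)


def compute_torsions(chain: BackboneChain) -> TorsionSeries:
    """Backbone φ/ψ for every residue of a chain, per continuous segment.

    φ(i) is the C(i-1)-N(i)-CA(i)-C(i) torsion, ψ(i) the
    N(i)-CA(i)-C(i)-N(i+1) torsion; both stay undefined at segment ends
    and around incomplete residues.
    """
    n = len(chain)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    N, CA, C = chain.coords["N"], chain.coords["CA"], chain.coords["C"]
    for start, stop in chain.segments():
        for i in range(start, stop):
            if i > start:
                phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
            if i < stop - 1:
                psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
    classes = [classify_phi_psi(phi[i], psi[i]) for i in range(n)]
    return TorsionSeries(chain.chain_id, phi, psi, classes)


@dataclass(frozen=True)
class HBondContact:
    """A backbone N-O contact within the hydrogen-bond cutoff."""

    donor: str       # residue label providing the amide N
    acceptor: str    # residue label providing the carbonyl O
    n_o_distance: float
    direction: str   # "N_i->O_j" or "N_j->O_i"


def backbone_hbonds(
    res_i: tuple[BackboneChain, int],
    res_j: tuple[BackboneChain, int],
    cutoff: float = HBOND_CUTOFF,
) -> list[HBondContact]:
    """Backbone hydrogen-bond contacts between two residues.

    Both directions, N(i)-O(j) and N(j)-O(i), are evaluated against the
    inclusive distance cutoff.  Residues are given as (chain, index)
    pairs; missing atoms yield an empty result with a warning.
    """
    chain_i, idx_i = res_i
    chain_j, idx_j = res_j
    contacts: list[HBondContact] = []
    pairs = [
        (chain_i, idx_i, chain_j, idx_j, "N_i->O_j"),
        (chain_j, idx_j, chain_i, idx_i, "N_j->O_i"),
    ]
    for dchain, didx, achain, aidx, direction in pairs:
        npos = dchain.atom("N", didx)
        opos = achain.atom("O", aidx)
        if not (np.isfinite(npos).all() and np.isfinite(opos).all()):
            warnings.warn(
                f"missing backbone atom on {dchain.residue_label(didx)} / "
                f"{achain.residue_label(aidx)}; no contact evaluated"
            )
            continue
        d = float(np.linalg.norm(npos - opos))
        if d <= cutoff:
            contacts.append(
                HBondContact(
                    donor=dchain.residue_label(didx),
                    acceptor=achain.residue_label(aidx),
                    n_o_distance=d,
                    direction=direction,
                )
            )
    return contacts


def torsion_table(chain: BackboneChain, torsions: TorsionSeries | None = None) -> pd.DataFrame:
    """Per-residue torsion/class table (TSV-ready)."""
    ts = torsions if torsions is not None else compute_torsions(chain)
    return pd.DataFrame(
        {
            "chain": chain.chain_id,
            "resnum": chain.seq_ids,
            "icode": chain.icodes,
            "aa": chain.aas,
            "phi": np.round(ts.phi, 3),
            "psi": np.round(ts.psi, 3),
            "class": ts.ss_class,
        }
    )
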