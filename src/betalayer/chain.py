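"""Backbone containers: chains of N/CA/C/O coordinates and structure models.

These are the substrate of all geometric analysis in the package.  A
:class:`BackboneChain` stores the four backbone heavy atoms per residue as
float arrays (NaN marks a missing atom) together with author residue
numbering, and knows where its peptide continuity breaks.  A
:class:`StructureModel` is an ordered set of chains plus the biological
assembly definitions carried over from the source file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

#: A C(i)-N(i+1) distance at or above this value (in Å) breaks the chain
#: into separate continuous segments; torsions are never computed across it.
CHAIN_BREAK_DISTANCE = 2.5

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class BackboneChain:
    """Ordered backbone of one polymer chain.

    Parameters
    ----------
    chain_id:
        Author chain identifier.
    seq_ids, icodes, aas:
        Author residue numbers, insertion codes and one-letter codes.
    coords:
        Mapping of atom name ("N", "CA", "C", "O") to an ``(n, 3)`` float
        array in Å.  Rows of NaN mark missing atoms; a residue missing any
        backbone atom is flagged incomplete and excluded from torsion
        computation.
    """

    def __init__(
        self,
        chain_id: str,
        seq_ids: list[int],
        icodes: list[str],
        aas: list[str],
        coords: dict[str, np.ndarray],
    ) -> None:
        n = len(seq_ids)
        if not (len(icodes) == len(aas) == n):
            raise ValueError("residue annotation lists must have equal length")
        self.chain_id = chain_id
        self.seq_ids = list(seq_ids)
        self.icodes = list(icodes)
        self.aas = list(aas)
        self.coords = {}
        for name in BACKBONE_ATOMS:
            arr = np.asarray(coords.get(name, np.full((n, 3), np.nan)), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"coordinate array {name} must have shape ({n}, 3)")
            self.coords[name] = arr

    def __len__(self) -> int:
        return len(self.seq_ids)

    @property
    def sequence(self) -> str:
        return "".join(self.aas)

    @property
    def ca(self) -> np.ndarray:
        return self.coords["CA"]

    def atom(self, name: str, index: int) -> np.ndarray:
        return self.coords[name][index]

    @property
    def complete_mask(self) -> np.ndarray:
        """Boolean mask of residues that have all four backbone atoms."""
        mask = np.ones(len(self), dtype=bool)
        for name in BACKBONE_ATOMS:
            mask &= np.isfinite(self.coords[name]).all(axis=1)
        return mask

    @property
    def gaps(self) -> list[int]:
        """Indices ``i`` where continuity breaks between ``i`` and ``i+1``."""
        out = []
        complete = self.complete_mask
        c = self.coords["C"]
        n = self.coords["N"]
        for i in range(len(self) - 1):
            if not (complete[i] and complete[i + 1]):
                out.append(i)
                continue
            if np.linalg.norm(n[i + 1] - c[i]) >= CHAIN_BREAK_DISTANCE:
                out.append(i)
        return out

    def segments(self) -> list[tuple[int, int]]:
        """Maximal continuous runs of complete residues as ``(start, stop)``.

        ``stop`` is exclusive.  Consecutive residues within a segment have
        all backbone atoms and a peptide C-N distance below the break
        threshold.
        """
        complete = self.complete_mask
        gap_after = set(self.gaps)
        segs: list[tuple[int, int]] = []
        start = None
        for i in range(len(self)):
            if complete[i] and start is None:
                start = i
            ends_here = (
                not complete[i]
                or i == len(self) - 1
                or i in gap_after
            )
            if start is not None and ends_here:
                stop = i + 1 if complete[i] else i
                if stop > start:
                    segs.append((start, stop))
                start = None
        return segs

    def residue_label(self, index: int) -> str:
        """Author-style residue label, e.g. ``A123`` or ``A123B``."""
        return f"{self.chain_id}{self.seq_ids[index]}{self.icodes[index]}"

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_id: str | None = None) -> "BackboneChain":
        """Copy with ``x -> R x + t`` applied to every atom."""
        coords = {
            name: arr @ np.asarray(rotation, dtype=float).T + translation
            for name, arr in self.coords.items()
        }
        return BackboneChain(
            chain_id if chain_id is not None else self.chain_id,
            self.seq_ids, self.icodes, self.aas, coords,
        )


@dataclass
class StructureModel:
    """A set of backbone chains from one model of a structure file."""

    identifier: str
    chains: list[BackboneChain]
    assembly_id: str | None = None
    #: assembly name -> list of (chain_ids, 4x4 transforms) generators,
    #: carried over from the source file for later expansion.
    assemblies: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain identifiers: {ids}")

    def chain(self, chain_id: str) -> BackboneChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.identifier,
            [c.transformed(rotation, translation) for c in self.chains],
            assembly_id=self.assembly_id,
            assemblies=self.assemblies,
        )
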