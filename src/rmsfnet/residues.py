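"""Residue identity model shared by every stage of the pipeline.

A residue at the pMHC interface is identified by its chain role (the short
peptide presented in the binding groove, or the MHC heavy chain) and its
author-assigned sequence position.  Positions are never re-indexed: peptide
residues run p1..p9 for a nonamer, heavy-chain residues keep the deposited
numbering.  When a position is mutated in silico between conditions (the
classic case being valine vs proline at peptide position 3), the two amino
acid identities are merged into one display label such as ``p3V/P`` so the
residue stays a single node across all trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

PEPTIDE = "peptide"
HEAVY = "heavy"

_CHAIN_ROLES = (PEPTIDE, HEAVY)


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Stable identifier for an interface residue.

    Ordering is lexicographic on ``(chain_role, position)`` which makes
    'heavy' sort before 'peptide'; this ordering is what the deterministic
    tie-breaks in the network code rely on.
    """

    chain_role: str
    position: int

    def __post_init__(self) -> None:
        if self.chain_role not in _CHAIN_ROLES:
            raise ValueError(f"chain_role must be one of {_CHAIN_ROLES}, got {self.chain_role!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:  # compact form used in file headers
        prefix = "p" if self.chain_role == PEPTIDE else "H"
        return f"{prefix}{self.position}"


def parse_residue_key(text: str) -> ResidueKey:
    """Inverse of ``str(key)``: 'p3' -> peptide 3, 'H155' -> heavy 155."""
    text = text.strip()
    if text.startswith("p"):
        return ResidueKey(PEPTIDE, int(text[1:]))
    if text.startswith("H"):
        return ResidueKey(HEAVY, int(text[1:]))
    raise ValueError(f"cannot parse residue key from {text!r}")


def make_label(
    key: ResidueKey,
    identities: Iterable[str] = (),
) -> str:
    """Display label for a residue given the amino-acid identities observed
    across trajectories (one letter per distinct identity, condition order).

    ``p3`` with identities ('V', 'P') -> 'p3V/P'; ``H155`` with ('H',) ->
    'H155' (heavy-chain labels keep the field's residue-letter+number
    convention only when a single identity is known).
    """
    idents = [i for i in identities if i]
    if key.chain_role == PEPTIDE:
        base = f"p{key.position}"
        if not idents:
            return base
        return base + "/".join(dict.fromkeys(idents))
    if len(set(idents)) == 1:
        return f"{idents[0]}{key.position}"
    return f"H{key.position}"


class SequentialNumbering:
    """Maps flat file residue numbers (as written by trajectory tools) onto
    ResidueKeys: heavy chain first (1..n_heavy), then peptide (1..n_peptide).
    """

    def __init__(self, n_heavy: int = 180, n_peptide: int = 9,
                 heavy_start: int = 1, peptide_start: int = 1):
        self.n_heavy = n_heavy
        self.n_peptide = n_peptide
        self.heavy_start = heavy_start
        self.peptide_start = peptide_start

    def key_for(self, file_number: int) -> ResidueKey:
        if 1 <= file_number <= self.n_heavy:
            return ResidueKey(HEAVY, self.heavy_start + file_number - 1)
        if self.n_heavy < file_number <= self.n_heavy + self.n_peptide:
            return ResidueKey(PEPTIDE, self.peptide_start + file_number - self.n_heavy - 1)
        raise ValueError(
            f"file residue number {file_number} outside the "
            f"{self.n_heavy}+{self.n_peptide} residue layout"
        )

    def keys(self) -> list[ResidueKey]:
        return [self.key_for(i) for i in range(1, self.n_heavy + self.n_peptide + 1)]


DEFAULT_MUTATED_POSITIONS: Mapping[ResidueKey, tuple[str, str]] = {
    ResidueKey(PEPTIDE, 3): ("V", "P"),
}
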