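"""Biosensor construct assembly.

An effector (e.g. circularly permuted GFP) is inserted into a scaffold
binding protein at residue i, meaning between scaffold positions i and
i+1. Following the established linker scheme for cpGFP insertions, the
N-terminal linker is res(i+1)-Ala-Ser and the C-terminal linker is
Ala-Ser-res(i), so residues i and i+1 each appear twice in the fusion:

    scaffold[1..i] · res(i+1)·A·S · effector · A·S·res(i) · scaffold[i+1..end]

Every construct is therefore exactly ``len(scaffold) + len(effector) + 6``
residues long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

__all__ = [
    "SensorConstruct",
    "build_sensor_sequence",
    "batch_design",
    "write_constructs_fasta",
    "read_fasta_sequence",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _validate_seq(seq: str, what: str) -> str:
    seq = seq.strip().upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"{what} contains non-amino-acid characters: {sorted(bad)}")
    if not seq:
        raise ValueError(f"{what} is empty")
    return seq


@dataclass
class SensorConstruct:
    scaffold_id: str
    scaffold_seq: str
    insertion_index: int  # 1-based residue i
    effector_id: str
    effector_seq: str
    full_seq: str

    @property
    def name(self) -> str:
        return f"{self.scaffold_id}_{self.insertion_index}-{self.effector_id}"

    def __post_init__(self) -> None:
        expected = len(self.scaffold_seq) + len(self.effector_seq) + 6
        if len(self.full_seq) != expected:
            raise ValueError(
                f"full_seq length {len(self.full_seq)} != scaffold+effector+6 "
                f"({expected})"
            )


def build_sensor_sequence(
    scaffold_seq: str,
    insertion_index: int,
    effector_seq: str,
    scaffold_id: str = "MBP",
    effector_id: str = "cpGFP",
) -> SensorConstruct:
    """Insert the effector cassette at scaffold residue ``insertion_index``.

    >>> build_sensor_sequence("MKLVNT", 3, "GGG").full_seq
    'MKLVASGGGASLVNT'
    """
    scaffold = _validate_seq(scaffold_seq, "scaffold")
    effector = _validate_seq(effector_seq, "effector")
    i = insertion_index
    if len(scaffold) < 2:
        raise ValueError("scaffold must have at least 2 residues")
    if not (1 <= i <= len(scaffold) - 1):
        raise ValueError(
            f"insertion index {i} out of range 1..{len(scaffold) - 1}"
        )
    # 0-based: scaffold[i-1] is residue i, scaffold[i] is residue i+1.
    full = (
        scaffold[:i]
        + scaffold[i]
        + "AS"
        + effector
        + "AS"
        + scaffold[i - 1]
        + scaffold[i:]
    )
    return SensorConstruct(
        scaffold_id=scaffold_id,
        scaffold_seq=scaffold,
        insertion_index=i,
        effector_id=effector_id,
        effector_seq=effector,
        full_seq=full,
    )


def batch_design(
    scaffold_seq: str,
    effector_seq: str,
    sites: Sequence[int],
    scaffold_id: str = "MBP",
    effector_id: str = "cpGFP",
) -> List[SensorConstruct]:
    """One construct per insertion site, in site order.

    Duplicate sites are collapsed with a warning.
    """
    seen: List[int] = []
    for s in sites:
        if s in seen:
            warnings.warn(f"duplicate insertion site {s} collapsed", stacklevel=2)
        else:
            seen.append(s)
    return [
        build_sensor_sequence(
            scaffold_seq, s, effector_seq, scaffold_id, effector_id
        )
        for s in seen
    ]


def write_constructs_fasta(constructs: Iterable[SensorConstruct], path) -> None:
    records = [
        SeqRecord(
            Seq(c.full_seq),
            id=c.name,
            description=(
                f"insertion_site={c.insertion_index} "
                f"scaffold_len={len(c.scaffold_seq)} "
                f"effector_len={len(c.effector_seq)}"
            ),
        )
        for c in constructs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequence(path) -> tuple:
    """(record id, amino-acid sequence) of the first FASTA record."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, _validate_seq(str(record.seq), f"sequence in {path}")
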