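"""Gapped template alignments with group membership (block-set / protect-set).

The toolkit consumes a pre-built multiple alignment (e.g. from MUSCLE or
MAFFT); it never aligns sequences itself. Group labels partition templates
into the *block-set* (templates the blocker should suppress) and the
*protect-set* (templates whose amplification must be preserved), plus any
free-form taxon labels.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .oligo import IUPAC_SETS

GAP = "-"
_VALID = set(IUPAC_SETS) | {GAP}

_GROUP_SUFFIX = re.compile(r"\|group=([^|\s]+)")


@dataclass
class TemplateAlignment:
    """Equal-length gapped IUPAC sequences with per-template group labels."""

    records: list[tuple[str, str]]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        for rid, seq in self.records:
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"invalid characters in {rid}: {sorted(bad)}")
        self._index = {rid: seq for rid, seq in self.records}

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, template_id: str) -> str:
        try:
            return self._index[template_id]
        except KeyError:
            raise KeyError(f"unknown template id {template_id!r}") from None

    def ids_in_group(self, group: str) -> list[str]:
        return [rid for rid in self.ids if self.groups.get(rid) == group]

    def column(self, col: int) -> str:
        """All characters in 1-based alignment column ``col``."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(seq[col - 1] for _, seq in self.records)


def read_alignment_fasta(path: str | Path | io.TextIOBase,
                         groups_tsv: str | Path | None = None) -> TemplateAlignment:
    """Read an aligned FASTA. Group labels come from a two-column TSV
    (id<TAB>group) or, failing that, a ``|group=NAME`` header suffix."""
    records: list[tuple[str, str]] = []
    groups: dict[str, str] = {}
    for rec in SeqIO.parse(path if isinstance(path, io.TextIOBase) else str(path), "fasta"):
        rid = rec.id
        m = _GROUP_SUFFIX.search(rid)
        if m:
            groups[rid[: m.start()]] = m.group(1)
            rid = rid[: m.start()]
        records.append((rid, str(rec.seq).upper().replace("U", "T")))
    if groups_tsv is not None:
        groups = {}
        for line in Path(groups_tsv).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, grp = line.split("\t")[:2]
            groups[rid] = grp
    return TemplateAlignment(records, groups)


def write_alignment_fasta(aln: TemplateAlignment, path: str | Path,
                          groups_tsv: str | Path | None = None) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta")
    if groups_tsv is not None:
        lines = [f"{rid}\t{aln.groups.get(rid, '')}" for rid in aln.ids]
        Path(groups_tsv).write_text("\n".join(lines) + "\n")
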