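"""Reference protein sets with keyword-tagged headers.

Headers carry a single structured field, ``keyword=<tag>``, which the
annotation module parses into the evidence used by the keyword classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple


@dataclass(frozen=True)
class ReferenceProtein:
    id: str
    protein: str
    keyword: str

    def __post_init__(self):
        if not self.protein:
            raise ValueError(f"reference {self.id}: empty protein")


@dataclass
class ReferenceDB:
    """An in-memory protein database with a name used in hit tables."""

    name: str
    records: List[ReferenceProtein] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reference ids: {dupes}")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self):
        return len(self.records)

    def __getitem__(self, rid: str) -> ReferenceProtein:
        return self._by_id[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    @property
    def total_residues(self) -> int:
        return sum(len(r.protein) for r in self.records)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id} keyword={r.keyword}\n{r.protein}\n")


def read_reference_fasta(path, name: str = "ref") -> ReferenceDB:
    """Parse a keyword-tagged reference FASTA back into a ReferenceDB."""
    records: List[ReferenceProtein] = []
    rid, kw, chunks = None, "", []

    def flush():
        if rid is not None:
            records.append(ReferenceProtein(rid, "".join(chunks), kw))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].split()
                rid, kw, chunks = head[0], "", []
                for token in head[1:]:
                    if token.startswith("keyword="):
                        kw = token[len("keyword="):]
            else:
                chunks.append(line)
    flush()
    return ReferenceDB(name=name, records=records)
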