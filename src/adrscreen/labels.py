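"""Drug-label exclusion: split screened signals into label-known and novel.

A signal already documented in the product label (clinical trials or
post-marketing surveillance sections) is not a novel finding; the knowledge
base is a user-supplied table of known (generic drug, preferred term) pairs.
Matching is exact on normalised vocabularies and disease-agnostic: a known
pair is excluded from every stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .registry import SignalResult

__all__ = ["LabelKnowledgeBase", "filter_novel"]


@dataclass
class LabelKnowledgeBase:
    """Set of label-known (generic_drug, preferred_term) pairs with provenance."""

    known_pairs: frozenset[tuple[str, str]]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], provenance: str = ""
    ) -> "LabelKnowledgeBase":
        pairs = frozenset((str(d), str(t)) for d, t in pairs)
        return cls(known_pairs=pairs, provenance={p: provenance for p in pairs})

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.known_pairs

    def __len__(self) -> int:
        return len(self.known_pairs)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [
            dict(generic_drug=d, preferred_term=t, provenance=self.provenance.get((d, t), ""))
            for d, t in sorted(self.known_pairs)
        ]
        pd.DataFrame(rows, columns=["generic_drug", "preferred_term", "provenance"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelKnowledgeBase":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        pairs = frozenset(
            (str(r.generic_drug), str(r.preferred_term)) for r in frame.itertuples(index=False)
        )
        prov = {
            (str(r.generic_drug), str(r.preferred_term)): str(getattr(r, "provenance", ""))
            for r in frame.itertuples(index=False)
        }
        return cls(known_pairs=pairs, provenance=prov)


def filter_novel(
    signals: Sequence[SignalResult], kb: LabelKnowledgeBase
) -> tuple[list[SignalResult], list[SignalResult]]:
    """Partition the *significant* input signals into (novel, label-known).

    Both partitions preserve the input order; non-significant inputs are not
    part of either partition.
    """
    novel: list[SignalResult] = []
    excluded: list[SignalResult] = []
    for signal in signals:
        if not signal.significant:
            continue
        if (signal.generic_drug, signal.preferred_term) in kb:
            excluded.append(signal)
        else:
            novel.append(signal)
    return novel, excluded
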