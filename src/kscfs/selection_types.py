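"""Containers shared by the filtering and subset-selection stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = ["GeneSubset", "RankedGenes"]


@dataclass(frozen=True)
class GeneSubset:
    """An ordered list of selected genes with provenance.

    ``parent`` records the upstream subset a selection was drawn from (e.g.
    the stage-1 candidate set of a two-stage pipeline); a subset with a
    parent must be contained in it.
    """

    gene_ids: tuple[str, ...]
    method: str = ""
    params: dict = field(default_factory=dict)
    parent: Optional["GeneSubset"] = None

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in subset")
        if self.parent is not None:
            missing = set(self.gene_ids) - set(self.parent.gene_ids)
            if missing:
                raise ValueError(f"genes not in parent subset: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["rank\tgene_id"]
        lines += [f"{i + 1}\t{g}" for i, g in enumerate(self.gene_ids)]
        Path(path).write_text("\n".join(lines) + "\n")
        side = Path(path).with_suffix(Path(path).suffix + ".prov.json")
        side.write_text(
            json.dumps(
                {"method": self.method, "params": self.params, "n_genes": len(self)},
                indent=2,
                sort_keys=True,
                default=str,
            )
            + "\n"
        )


@dataclass(frozen=True)
class RankedGenes:
    """Genes ordered best-first with aligned, nonincreasing scores."""

    gene_ids: tuple[str, ...]
    scores: tuple[float, ...]
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if any(a < b - 1e-12 for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be nonincreasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> "RankedGenes":
        return RankedGenes(self.gene_ids[:k], self.scores[:k], self.method, self.params)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["rank\tgene_id\tscore"]
        lines += [
            f"{i + 1}\t{g}\t{s:.10g}"
            for i, (g, s) in enumerate(zip(self.gene_ids, self.scores))
        ]
        Path(path).write_text("\n".join(lines) + "\n")
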