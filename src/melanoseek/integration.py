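"""Merge evidence records from all sources into per-gene provenance profiles.

The integration step answers, for every gene or protein, *which* of the five
evidence sources (GWAS, PheWAS, metabolomics, transcriptomics, biomedical)
reported it, how often, and at what best p-value where applicable — the
accounting behind a five-set Venn breakdown of the disease gene set — and
emits the unified gene/protein set that seeds drug-target mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .types import EvidenceRecord, P_VALUE_SOURCES, Source

PathLike = Union[str, Path]


@dataclass
class GeneEvidenceProfile:
    """Provenance of one gene across the five evidence sources."""

    gene: str
    sources: set[Source] = field(default_factory=set)
    best_p: dict[Source, float] = field(default_factory=dict)
    n_records: dict[Source, int] = field(default_factory=dict)


def build_profiles(records: Iterable[EvidenceRecord]) -> dict[str, GeneEvidenceProfile]:
    """Aggregate harmonized evidence records into one profile per gene."""
    profiles: dict[str, GeneEvidenceProfile] = {}
    for rec in records:
        prof = profiles.setdefault(rec.gene, GeneEvidenceProfile(gene=rec.gene))
        prof.sources.add(rec.source)
        prof.n_records[rec.source] = prof.n_records.get(rec.source, 0) + 1
        if rec.p_value is not None and rec.source in P_VALUE_SOURCES:
            prev = prof.best_p.get(rec.source)
            if prev is None or rec.p_value < prev:
                prof.best_p[rec.source] = rec.p_value
    return profiles


def venn_counts(
    profiles: Mapping[str, GeneEvidenceProfile],
) -> dict[frozenset[Source], int]:
    """Count genes per exact source combination (the 31 non-empty subsets).

    Returns a map from source subset to the number of genes observed in
    exactly that subset; counts sum to the number of profiles.
    """
    counts: dict[frozenset[Source], int] = {}
    for prof in profiles.values():
        key = frozenset(prof.sources)
        counts[key] = counts.get(key, 0) + 1
    return counts


def multi_source_total(counts: Mapping[frozenset[Source], int]) -> int:
    """Number of genes supported by two or more sources."""
    return sum(n for combo, n in counts.items() if len(combo) >= 2)


def unified_gene_set(
    profiles: Mapping[str, GeneEvidenceProfile], min_sources: int = 1
) -> list[str]:
    """Lexicographically sorted genes backed by at least ``min_sources`` sources."""
    if min_sources < 1:
        raise ValueError(f"min_sources must be >= 1, got {min_sources}")
    return sorted(g for g, p in profiles.items() if len(p.sources) >= min_sources)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_unified_set(
    profiles: Mapping[str, GeneEvidenceProfile],
    genes_path: PathLike,
    sidecar_path: PathLike,
    min_sources: int = 1,
) -> None:
    """Write the unified set (one-column TSV) and a provenance sidecar TSV."""
    genes = unified_gene_set(profiles, min_sources)
    pd.DataFrame({"gene": genes}).to_csv(genes_path, sep="\t", index=False)
    rows = []
    for g in genes:
        prof = profiles[g]
        rows.append(
            {
                "gene": g,
                "sources": ";".join(sorted(s.value for s in prof.sources)),
                "best_p": ";".join(
                    f"{s.value}={prof.best_p[s]:.4g}" for s in sorted(prof.best_p, key=lambda x: x.value)
                ),
                "n_records": sum(prof.n_records.values()),
            }
        )
    pd.DataFrame(rows, columns=["gene", "sources", "best_p", "n_records"]).to_csv(
        sidecar_path, sep="\t", index=False
    )


def venn_counts_to_json(counts: Mapping[frozenset[Source], int], path: PathLike) -> None:
    serializable = {
        "+".join(sorted(s.value for s in combo)): n for combo, n in counts.items()
    }
    with open(path, "w") as fh:
        json.dump(
            {
                "combinations": dict(sorted(serializable.items())),
                "total_genes": sum(counts.values()),
                "multi_source_total": multi_source_total(counts),
            },
            fh,
            indent=2,
        )
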