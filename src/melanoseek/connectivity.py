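"""Connectivity-map style scoring of drug expression signatures.

Each drug *instance* (one treatment of one cell line) is a ranked list of the
gene universe, position 1 = most up-regulated.  A disease query is a pair of
tag sets (up- and down-regulated genes).  Scoring follows the rank-based
Kolmogorov-Smirnov enrichment statistic used by the Connectivity Map:

With ``V(1) <= ... <= V(t)`` the ascending rank positions of the ``t`` tag
genes in a list of length ``n``,

    a = max_j [ j/t - V(j)/n ]
    b = max_j [ V(j)/n - (j-1)/t ]
    ES = a  if a > b  else  -b

so tags concentrated at the top give ES near +1 and at the bottom near -1.
A per-instance connectivity score combines the up- and down-tag ES (zeroed
when they agree in sign, hence non-informative) and is rescaled across the
whole instance collection so the extreme raw scores map to exactly +/-1.
Per-drug results carry the mean over instances and a second-level KS
enrichment of the drug's instances within the score-ordered instance list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

PathLike = Union[str, Path]


@dataclass
class RankedSignature:
    """One drug instance: a strict ranking of the gene universe."""

    instance_id: str
    drug: str
    cell_line: str
    ranking: tuple[str, ...]  # position 1 (index 0) = most up-regulated

    def __post_init__(self) -> None:
        n = len(self.ranking)
        if n < 2:
            raise ValueError(f"{self.instance_id}: universe size must be >= 2, got {n}")
        if len(set(self.ranking)) != n:
            raise ValueError(f"{self.instance_id}: ranking is not a permutation (duplicate genes)")

    @property
    def n(self) -> int:
        return len(self.ranking)

    def positions(self, tags: Iterable[str], skip_missing: bool = False) -> list[int]:
        """1-based rank positions of the tag genes, ascending."""
        index = {g: i + 1 for i, g in enumerate(self.ranking)}
        pos = []
        for g in tags:
            if g not in index:
                if skip_missing:
                    continue
                raise KeyError(f"tag gene {g!r} not in signature universe")
            pos.append(index[g])
        return sorted(pos)


@dataclass(frozen=True)
class TagSet:
    """Up- and down-regulated query gene sets."""

    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"up/down tag sets overlap: {sorted(self.up & self.down)[:3]}")
        if not self.up and not self.down:
            raise ValueError("both tag sets empty")


@dataclass
class ConnectivityResult:
    """Per-drug aggregate over its scored instances."""

    drug: str
    instance_scores: dict[str, float] = field(default_factory=dict)
    mean: float = 0.0
    enrichment: float = 0.0

    @property
    def n_instances(self) -> int:
        return len(self.instance_scores)


def ks_enrichment_positions(positions: Sequence[int], n: int) -> float:
    """KS enrichment from ascending 1-based positions of t tags in a list of n."""
    t = len(positions)
    if t == 0:
        raise ValueError("no tag positions given")
    if n < 1 or positions[0] < 1 or positions[-1] > n:
        raise ValueError("positions out of range")
    a = max(j / t - v / n for j, v in enumerate(positions, start=1))
    b = max(v / n - (j - 1) / t for j, v in enumerate(positions, start=1))
    return a if a > b else -b


def ks_enrichment(
    tags: Iterable[str], signature: RankedSignature, skip_missing: bool = False
) -> float:
    """KS enrichment score of a tag gene set within one ranked signature."""
    tags = list(tags)
    if not tags:
        raise ValueError("empty tag set")
    pos = signature.positions(tags, skip_missing=skip_missing)
    if not pos:
        raise ValueError("no tag genes present in signature universe")
    return ks_enrichment_positions(pos, signature.n)


def raw_connectivity(
    tags: TagSet, signature: RankedSignature, skip_missing: bool = False
) -> float:
    """Unscaled per-instance connectivity score.

    With both sides present: 0 when ES_up and ES_down share a sign, else
    ES_up - ES_down.  With one side empty the score is the ES of the
    non-empty side.
    """
    if tags.up and tags.down:
        es_up = ks_enrichment(tags.up, signature, skip_missing)
        es_down = ks_enrichment(tags.down, signature, skip_missing)
        if es_up * es_down > 0:
            return 0.0
        return es_up - es_down
    side = tags.up if tags.up else tags.down
    return ks_enrichment(side, signature, skip_missing)


def scale_scores(raws: Mapping[str, float]) -> dict[str, float]:
    """Batch-rescale raw scores to [-1, 1].

    Positive raws are divided by the maximum positive raw, negative raws by
    the magnitude of the minimum negative raw, so each extreme maps to
    exactly +/-1; zeros stay zero.
    """
    values = list(raws.values())
    max_pos = max((v for v in values if v > 0), default=None)
    min_neg = min((v for v in values if v < 0), default=None)
    out = {}
    for k, v in raws.items():
        if v > 0:
            out[k] = v / max_pos
        elif v < 0:
            out[k] = v / abs(min_neg)
        else:
            out[k] = 0.0
    return out


def connectivity_scores(
    tags: TagSet, signatures: Iterable[RankedSignature], skip_missing: bool = False
) -> dict[str, float]:
    """Scaled connectivity score per instance across the whole collection."""
    raws = {sig.instance_id: raw_connectivity(tags, sig, skip_missing) for sig in signatures}
    return scale_scores(raws)


def aggregate_drugs(
    scores: Mapping[str, float], instance_drug: Mapping[str, str]
) -> dict[str, ConnectivityResult]:
    """Aggregate instance scores per drug: arithmetic mean + instance-level KS.

    The enrichment is the KS statistic of a drug's instance positions within
    all instances ordered by descending score (deterministic tie-break on
    instance id), so a drug whose instances cluster among the top-scoring
    instances gets positive enrichment, consistent with the sign of the mean.
    """
    ordered = sorted(scores, key=lambda i: (-scores[i], i))
    position = {inst: i + 1 for i, inst in enumerate(ordered)}
    n = len(ordered)
    results: dict[str, ConnectivityResult] = {}
    for inst, score in scores.items():
        drug = instance_drug[inst]
        results.setdefault(drug, ConnectivityResult(drug=drug)).instance_scores[inst] = score
    for res in results.values():
        vals = list(res.instance_scores.values())
        res.mean = sum(vals) / len(vals)
        pos = sorted(position[i] for i in res.instance_scores)
        res.enrichment = ks_enrichment_positions(pos, n) if n >= 2 else 0.0
    return results


@dataclass
class SelectionResult:
    retained: list[ConnectivityResult] = field(default_factory=list)
    rejected: list[ConnectivityResult] = field(default_factory=list)
    not_in_cmap: list[str] = field(default_factory=list)


def select_candidates(
    results: Mapping[str, ConnectivityResult],
    anchors_pos: Iterable[str],
    anchors_neg: Iterable[str] = (),
    min_abs_mean: float = 0.0,
    candidates: Optional[Iterable[str]] = None,
) -> SelectionResult:
    """Select drugs whose connectivity agrees with the positive anchors.

    A drug is retained iff sign(mean) equals the sign of the positive-anchor
    mean, differs from the negative-anchor mean's sign (when negative anchors
    are given), and |mean| >= min_abs_mean.  ``candidates`` restricts scoring
    to a drug list; candidates absent from the signature panel are reported
    as NOT_IN_CMAP and dropped.  Output ordering is deterministic (by drug).
    """
    anchors_pos = list(anchors_pos)
    anchors_neg = list(anchors_neg)
    if not anchors_pos:
        raise ValueError("anchors_pos must not be empty")
    for anchor in anchors_pos + anchors_neg:
        if anchor not in results:
            raise KeyError(f"anchor drug {anchor!r} not in results")
    pos_mean = sum(results[a].mean for a in anchors_pos) / len(anchors_pos)
    pos_sign = math.copysign(1.0, pos_mean) if pos_mean != 0 else 0.0
    neg_sign = 0.0
    if anchors_neg:
        neg_mean = sum(results[a].mean for a in anchors_neg) / len(anchors_neg)
        neg_sign = math.copysign(1.0, neg_mean) if neg_mean != 0 else 0.0
        if neg_sign == pos_sign:
            raise ValueError(
                "conflicting anchors: positive and negative anchor means share a sign"
            )
    anchor_names = set(anchors_pos) | set(anchors_neg)
    if candidates is not None:
        pool = []
        out = SelectionResult()
        for drug in sorted(set(candidates)):
            if drug in results:
                pool.append(results[drug])
            else:
                out.not_in_cmap.append(drug)
    else:
        out = SelectionResult()
        pool = [results[d] for d in sorted(results) if d not in anchor_names]
    for res in sorted(pool, key=lambda r: r.drug):
        sign = math.copysign(1.0, res.mean) if res.mean != 0 else 0.0
        ok = (
            sign == pos_sign
            and (not anchors_neg or sign != neg_sign)
            and abs(res.mean) >= min_abs_mean
        )
        (out.retained if ok else out.rejected).append(res)
    return out


# ---------------------------------------------------------------------------
# File formats: RNK signatures with an instance manifest, GMT tag sets
# ---------------------------------------------------------------------------

def write_rnk(signature: RankedSignature, path: PathLike) -> None:
    """Write a two-column RNK file (gene, descending score; top rank first)."""
    n = signature.n
    with open(path, "w") as fh:
        for i, gene in enumerate(signature.ranking):
            fh.write(f"{gene}\t{n - i}\n")


def read_rnk(path: PathLike, instance_id: str, drug: str, cell_line: str = "") -> RankedSignature:
    genes, scores = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, score = line.split("\t")
        genes.append(gene)
        scores.append(float(score))
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return RankedSignature(
        instance_id=instance_id,
        drug=drug,
        cell_line=cell_line,
        ranking=tuple(genes[i] for i in order),
    )


def write_manifest(signatures: Iterable[RankedSignature], paths: Mapping[str, str], out: PathLike) -> None:
    rows = [
        {"instance_id": s.instance_id, "drug": s.drug, "cell_line": s.cell_line,
         "file": paths[s.instance_id]}
        for s in signatures
    ]
    pd.DataFrame(rows, columns=["instance_id", "drug", "cell_line", "file"]).to_csv(
        out, sep="\t", index=False
    )


def read_signature_panel(manifest_path: PathLike) -> list[RankedSignature]:
    """Read all instances listed in a manifest TSV (file paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    sigs = []
    for _, row in df.iterrows():
        rnk = manifest_path.parent / row["file"]
        sigs.append(
            read_rnk(rnk, row["instance_id"], row["drug"], row.get("cell_line", "") or "")
        )
    return sigs


def write_gmt(sets: Mapping[str, Iterable[str]], path: PathLike, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(set(genes))]) + "\n")


def read_gmt(path: PathLike) -> dict[str, frozenset[str]]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        out[parts[0]] = frozenset(parts[2:])
    return out


def read_tagset(path: PathLike, up_name: str = "up", down_name: str = "down") -> TagSet:
    sets = read_gmt(path)
    return TagSet(
        up=sets.get(up_name, frozenset()), down=sets.get(down_name, frozenset())
    )


def write_results(
    results: Mapping[str, ConnectivityResult], decisions: Mapping[str, str], path: PathLike
) -> None:
    rows = [
        {
            "drug": r.drug,
            "mean": f"{r.mean:.6f}",
            "enrichment": f"{r.enrichment:.6f}",
            "n": r.n_instances,
            "decision": decisions.get(r.drug, ""),
        }
        for r in sorted(results.values(), key=lambda r: r.drug)
    ]
    pd.DataFrame(rows, columns=["drug", "mean", "enrichment", "n", "decision"]).to_csv(
        path, sep="\t", index=False
    )
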