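"""Gene signatures, set algebra, UpSet-style overlap and count-table reports.

The consensus tissue-resident memory (T_RM) signature is the intersection of
per-tissue temporal gene sets; subtracting the circulating-memory (T_CIRC)
consensus yields the temporal T_RM signature.  Overlaps against published
signatures are reported with exclusive-intersection (UpSet) semantics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .containers import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with provenance.

    Gene identity is exact string match after whitespace trimming; duplicates
    are collapsed order-preserving.  ``uppercase()`` provides a symbol-level
    mouse-to-human matching mode (documented as symbol matching only, not
    true orthology).
    """

    name: str
    genes: tuple[str, ...]
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValidationError(f"signature {self.name!r} needs non-empty provenance")
        seen, cleaned = set(), []
        for g in self.genes:
            g = str(g).strip()
            if g and g not in seen:
                seen.add(g)
                cleaned.append(g)
        object.__setattr__(self, "genes", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def uppercase(self) -> "GeneSignature":
        """Symbol-matching mode for cross-species (mouse->human) comparison."""
        return GeneSignature(
            self.name,
            tuple(g.upper() for g in self.genes),
            {**dict(self.provenance), "symbol_mode": "uppercase"},
        )


def consensus_signature(
    sig_a: GeneSignature, sig_b: GeneSignature, name: str | None = None
) -> tuple[GeneSignature, dict[str, int]]:
    """Intersection of two signatures plus shared/unique counts."""
    if not len(sig_a) or not len(sig_b):
        raise ValidationError("consensus requires two non-empty signatures")
    shared = sorted(sig_a.gene_set & sig_b.gene_set)
    counts = {
        "shared": len(shared),
        "unique_a": len(sig_a) - len(shared),
        "unique_b": len(sig_b) - len(shared),
    }
    sig = GeneSignature(
        name or f"consensus({sig_a.name},{sig_b.name})",
        tuple(shared),
        {
            "derivation": "consensus_signature",
            "parents": (sig_a.name, sig_b.name),
            **counts,
        },
    )
    return sig, counts


def subtract_circulating(
    consensus_trm: GeneSignature,
    consensus_tcirc: GeneSignature,
    name: str | None = None,
) -> tuple[GeneSignature, int]:
    """Remove circulating-memory genes from the resident consensus."""
    removed = consensus_trm.gene_set & consensus_tcirc.gene_set
    kept = sorted(consensus_trm.gene_set - removed)
    if not kept:
        logger.warning(
            "circulating signature covers the whole consensus; result is empty"
        )
    sig = GeneSignature(
        name or f"{consensus_trm.name}_minus_{consensus_tcirc.name}",
        tuple(kept),
        {
            "derivation": "subtract_circulating",
            "parents": (consensus_trm.name, consensus_tcirc.name),
            "n_removed": len(removed),
        },
    )
    return sig, len(removed)


@dataclass
class OverlapReport:
    """Exclusive-intersection (UpSet) counts over >= 2 signatures."""

    names: tuple[str, ...]
    exclusive: dict[frozenset, int]
    totals: dict[str, int]
    union_size: int
    in_all: int
    in_ge1_other: dict[str, int]

    def __post_init__(self) -> None:
        assert sum(self.exclusive.values()) == self.union_size
        for name in self.names:
            assert self.totals[name] == sum(
                n for combo, n in self.exclusive.items() if name in combo
            )


def overlap_matrix(signatures: Sequence[GeneSignature]) -> OverlapReport:
    """Exclusive-intersection counts for every non-empty combination."""
    if len(signatures) < 2:
        raise ValidationError("need at least 2 signatures for an overlap report")
    if len(signatures) > 10:
        raise ConfigurationError("more than 10 signatures (combinatorial guard)")
    names = tuple(s.name for s in signatures)
    if len(set(names)) != len(names):
        raise ValidationError("signature names must be unique for overlap reporting")
    sets = {s.name: s.gene_set for s in signatures}
    membership: dict[str, frozenset] = {}
    for gene in frozenset().union(*sets.values()):
        membership[gene] = frozenset(n for n in names if gene in sets[n])
    exclusive = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    for combo in membership.values():
        exclusive[combo] += 1
    exclusive = {c: n for c, n in exclusive.items() if n > 0}
    totals = {n: len(sets[n]) for n in names}
    in_all = len(frozenset.intersection(*(frozenset(v) for v in sets.values())))
    in_ge1_other = {
        n: sum(1 for g in sets[n] if len(membership[g]) > 1) for n in names
    }
    return OverlapReport(
        names=names,
        exclusive=exclusive,
        totals=totals,
        union_size=len(membership),
        in_all=in_all,
        in_ge1_other=in_ge1_other,
    )


def validate_count_table(table: Mapping[str, int], total_key: str) -> None:
    if total_key not in table:
        raise ValidationError(f"total key {total_key!r} missing from count table")
    total = table[total_key]
    if total <= 0:
        raise ValidationError("count-table total must be positive")
    for key, value in table.items():
        if value < 0:
            raise ValidationError(f"negative count for {key!r}")
        if value > total:
            raise ValidationError(f"sub-count {key!r}={value} exceeds total {total}")


def proportion_report(
    table: Mapping[str, int],
    total_key: str,
    part_keys: Iterable[str] = (),
    union_pairs: Iterable[tuple[str, str, str]] = (),
) -> dict[str, dict]:
    """Percentages of named counts, at 1 decimal, with exact fractions kept.

    ``union_pairs`` entries are ``(a_key, b_key, both_key)``: the percentage
    of cells positive for *both* markers among those positive for *either*
    (denominator by inclusion-exclusion, A + B - AB).
    """
    validate_count_table(table, total_key)
    total = table[total_key]
    report: dict[str, dict] = {}
    for key in part_keys:
        if key not in table:
            raise ValidationError(f"part key {key!r} missing from count table")
        frac = Fraction(table[key], total)
        report[key] = {
            "count": table[key],
            "denominator": total,
            "fraction": frac,
            "pct": round(100.0 * table[key] / total, 1),
        }
    for a_key, b_key, both_key in union_pairs:
        a, b, ab = table[a_key], table[b_key], table[both_key]
        if ab > min(a, b):
            raise ValidationError(
                f"double-positive {both_key!r}={ab} exceeds min({a_key}, {b_key})"
            )
        denom = a + b - ab
        if denom <= 0:
            raise ValidationError("empty union denominator")
        frac = Fraction(ab, denom)
        report[f"{both_key}_of_either"] = {
            "count": ab,
            "denominator": denom,
            "fraction": frac,
            "pct": round(100.0 * ab / denom, 1),
        }
    return report


# ---------------------------------------------------------------------------
# signature I/O: 2-column TSV and GMT interchange


def write_signatures_tsv(signatures: Sequence[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsignature_name\n")
        for sig in signatures:
            for gene in sig.genes:
                fh.write(f"{gene}\t{sig.name}\n")


def read_signatures_tsv(path) -> list[GeneSignature]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "signature_name"]:
            raise ValidationError(f"unexpected signature TSV header in {path}")
        for line in fh:
            gene, name = line.rstrip("\n").split("\t")[:2]
            sets.setdefault(name, []).append(gene)
    return [
        GeneSignature(name, tuple(genes), {"source": str(path)})
        for name, genes in sets.items()
    ]


def write_gmt(signatures: Sequence[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            desc = str(dict(sig.provenance).get("derivation", "trmtime"))
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


def read_gmt(path) -> list[GeneSignature]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed GMT line in {path}: {line[:60]!r}")
        out.append(
            GeneSignature(fields[0], tuple(fields[2:]), {"source": str(path), "description": fields[1]})
        )
    return out
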