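"""OTU lineage tables and dereplication parameter sets.

File formats (both UTF-8, ``#`` starts a comment line, blank lines
are ignored):

Taxonomy TSV -- one OTU per line::

    <otu_name>\t<rank1>;<rank2>;...;<rankK>

Lineages are positional: rank 1 is the most inclusive label.  Labels
need not be real taxonomic ranks -- sample sites, project tags or any
user-defined categories work the same way.

Parameter file -- line-oriented::

    threshold\t<float>
    rule\t<category>\t<rank>\t<retain>
    default\t<rank>\t<retain>

``threshold`` is required and appears once.  ``rule`` lines may repeat;
no two may share the same (category, rank).  At most one ``default``
line; it applies to any clade whose OTUs all share one label at the
given rank and that no explicit rule covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Iterable, Optional, Union

from .errors import ValidationError

TextSource = Union[str, IO[str], Iterable[str]]


def _lines(source: TextSource) -> Iterable[str]:
    if isinstance(source, str):
        return StringIO(source)
    return source


@dataclass(frozen=True)
class DereplicationRule:
    """Keep ``retain`` OTUs per clade unanimous for ``category`` at ``rank``."""

    category: str
    rank: int
    retain: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"rule rank must be >= 1, got {self.rank}")
        if self.retain < 1:
            raise ValidationError(f"rule retain must be >= 1, got {self.retain}")


@dataclass
class TrimParams:
    """Support threshold plus the dereplication rule set."""

    support_threshold: float
    rules: list[DereplicationRule] = field(default_factory=list)
    default_rule: Optional[tuple[int, int]] = None  # (rank, retain)

    def __post_init__(self) -> None:
        if self.support_threshold < 0:
            raise ValidationError(
                f"support threshold must be >= 0, got {self.support_threshold}"
            )
        seen: set[tuple[str, int]] = set()
        for rule in self.rules:
            key = (rule.category, rule.rank)
            if key in seen:
                raise ValidationError(
                    f"duplicate rule for (category, rank) = {key!r}"
                )
            seen.add(key)
        if self.default_rule is not None:
            rank, retain = self.default_rule
            if rank < 1 or retain < 1:
                raise ValidationError(
                    f"default rule rank and retain must be >= 1, got {self.default_rule}"
                )


@dataclass
class TaxonomyMap:
    """Mapping OTU name -> ordered lineage, most inclusive rank first."""

    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __contains__(self, otu: str) -> bool:
        return otu in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_taxonomy(source: TextSource) -> TaxonomyMap:
    """Read a taxonomy TSV (see module docs) into a :class:`TaxonomyMap`."""
    entries: dict[str, tuple[str, ...]] = {}
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"taxonomy line {lineno}: expected 2 tab-separated fields, "
                f"got {len(parts)}"
            )
        otu, lineage_str = parts[0].strip(), parts[1].strip()
        if not otu:
            raise ValidationError(f"taxonomy line {lineno}: empty OTU name")
        if otu in entries:
            raise ValidationError(
                f"taxonomy line {lineno}: duplicate OTU name {otu!r}"
            )
        lineage = tuple(label.strip() for label in lineage_str.split(";"))
        if not lineage_str or any(not label for label in lineage):
            raise ValidationError(
                f"taxonomy line {lineno}: empty lineage label for OTU {otu!r}"
            )
        entries[otu] = lineage
    return TaxonomyMap(entries=entries)


def serialize_taxonomy(taxonomy: TaxonomyMap) -> str:
    """Inverse of :func:`load_taxonomy` (entry order preserved)."""
    return "".join(
        f"{otu}\t{';'.join(lineage)}\n" for otu, lineage in taxonomy.entries.items()
    )


def load_params(source: TextSource) -> TrimParams:
    """Read a parameter file (see module docs) into :class:`TrimParams`."""
    threshold: Optional[float] = None
    rules: list[DereplicationRule] = []
    default_rule: Optional[tuple[int, int]] = None
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        kind = parts[0].strip()
        try:
            if kind == "threshold":
                if len(parts) != 2:
                    raise ValidationError("expected: threshold\\t<float>")
                if threshold is not None:
                    raise ValidationError("threshold specified twice")
                threshold = float(parts[1])
            elif kind == "rule":
                if len(parts) != 4:
                    raise ValidationError(
                        "expected: rule\\t<category>\\t<rank>\\t<retain>"
                    )
                rules.append(
                    DereplicationRule(
                        category=parts[1].strip(),
                        rank=int(parts[2]),
                        retain=int(parts[3]),
                    )
                )
            elif kind == "default":
                if len(parts) != 3:
                    raise ValidationError("expected: default\\t<rank>\\t<retain>")
                if default_rule is not None:
                    raise ValidationError("default rule specified twice")
                default_rule = (int(parts[1]), int(parts[2]))
            else:
                raise ValidationError(f"unknown directive {kind!r}")
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"params line {lineno}: {exc}") from None
    if threshold is None:
        raise ValidationError("params file is missing a 'threshold' line")
    return TrimParams(
        support_threshold=threshold, rules=rules, default_rule=default_rule
    )


def serialize_params(params: TrimParams) -> str:
    """Inverse of :func:`load_params`."""
    out = [f"threshold\t{params.support_threshold}\n"]
    for rule in params.rules:
        out.append(f"rule\t{rule.category}\t{rule.rank}\t{rule.retain}\n")
    if params.default_rule is not None:
        rank, retain = params.default_rule
        out.append(f"default\t{rank}\t{retain}\n")
    return "".join(out)


def category_at_rank(
    taxonomy: TaxonomyMap, otu: str, rank: int
) -> Optional[str]:
    """Lineage label of ``otu`` at 1-based ``rank``; ``None`` when absent.

    Absent means: the OTU is unmapped, or its lineage is shorter than
    ``rank``.  Absence is a value, not an error.
    """
    lineage = taxonomy.entries.get(otu)
    if lineage is None or len(lineage) < rank:
        return None
    return lineage[rank - 1]


def matching_rule(
    params: TrimParams,
    taxonomy: TaxonomyMap,
    leaf_set: Iterable[str],
) -> Optional[DereplicationRule]:
    """The rule unanimously satisfied by every OTU in ``leaf_set``, if any.

    Explicit rules are checked first; when several match, the deepest
    rank wins and, among equal ranks, the first-declared rule.  The
    default rule applies only when no explicit rule does, and matches
    when all OTUs share one non-absent label at the default rank (the
    returned rule carries that shared label as its category).  Any OTU
    with an absent category at the tested rank disqualifies that rule.
    """
    leaves = list(leaf_set)
    if not leaves:
        raise ValidationError("matching_rule requires a non-empty leaf set")
    best: Optional[DereplicationRule] = None
    for rule in params.rules:
        if all(
            category_at_rank(taxonomy, otu, rule.rank) == rule.category
            for otu in leaves
        ):
            if best is None or rule.rank > best.rank:
                best = rule
    if best is not None:
        return best
    if params.default_rule is not None:
        rank, retain = params.default_rule
        labels = {category_at_rank(taxonomy, otu, rank) for otu in leaves}
        if len(labels) == 1:
            (label,) = labels
            if label is not None:
                return DereplicationRule(category=label, rank=rank, retain=retain)
    return None
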