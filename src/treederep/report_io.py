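"""Serialization of trim results.

Three outputs:

* retained-OTU list -- one OTU per line (the functional contract),
  followed by a ``#``-prefixed per-clade summary block;
* trimmed reference tree -- a Newick cladogram over the retained
  leaves, for visual reference only (its topology is induced, not
  re-estimated, and it carries no branch lengths);
* removal table -- a machine-readable TSV, one row per processed clade.

All outputs are deterministic: byte-identical across repeated runs on
identical inputs.
"""

from __future__ import annotations

from .errors import ValidationError
from .newick_io import Tree, restrict_to_leaves, write_newick
from .dereplicator import TrimResult


def _fmt_support(value) -> str:
    return "NA" if value is None else str(float(value))


def write_retained_list(result: TrimResult) -> str:
    """Retained OTU names, one per line, plus a commented summary block."""
    lines = [f"{name}\n" for name in result.retained_otus]
    lines.append("#\n")
    lines.append(
        f"# clades dereplicated: {len(result.records)}; "
        f"OTUs removed: {result.total_removed}\n"
    )
    lines.append(
        "# category\trank\tclade_size\tretained\tremoved\tsupport\tmedian\n"
    )
    for rec in result.records:
        lines.append(
            f"# {rec.category}\t{rec.rank}\t{len(rec.clade_leaves)}\t"
            f"{len(rec.retained)}\t{rec.removed_count}\t"
            f"{_fmt_support(rec.support)}\t{rec.median}\n"
        )
    return "".join(lines)


def read_retained_list(text: str) -> list[str]:
    """Recover the retained OTU names from :func:`write_retained_list` output."""
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_reference_tree(tree: Tree, result: TrimResult) -> str:
    """Newick cladogram of the input topology restricted to retained leaves."""
    if len(result.retained_otus) < 2:
        raise ValidationError(
            "cannot write a reference tree with fewer than 2 retained OTUs"
        )
    trimmed = restrict_to_leaves(tree, set(result.retained_otus))
    return write_newick(trimmed, with_branch_lengths=False, with_supports=True)


REMOVAL_TABLE_COLUMNS = (
    "category",
    "rank",
    "support",
    "clade_size",
    "retained_names",
    "removed_count",
    "median",
)


def write_removal_table(result: TrimResult) -> str:
    """TSV with one row per removal record (header always present)."""
    lines = ["\t".join(REMOVAL_TABLE_COLUMNS) + "\n"]
    for rec in result.records:
        lines.append(
            "\t".join(
                (
                    rec.category,
                    str(rec.rank),
                    _fmt_support(rec.support),
                    str(len(rec.clade_leaves)),
                    ";".join(rec.retained),
                    str(rec.removed_count),
                    str(rec.median),
                )
            )
            + "\n"
        )
    return "".join(lines)
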