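"""Join bound-gene sets with expression responses: direct-target fractions
and two-digit binding x induction response classes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .peaks import PeakGeneAssignment
from .expr import PatternCode

#: Fixed label table for the two-digit response codes.  The first digit is
#: the trajectory without induction, the second the trajectory under
#: induction (1 up, 0 down, 2 invariant).
RESPONSE_LABELS: dict[str, str] = {
    "00": "still_downregulated",
    "01": "reversed",
    "02": "not_downregulated",
    "10": "reversed",
    "11": "still_upregulated",
    "12": "not_upregulated",
    "20": "downregulated",
    "21": "upregulated",
    "22": "unresponsive",
}


@dataclass(frozen=True)
class ResponseClass:
    gene_id: str
    code: str
    label: str

    def __post_init__(self) -> None:
        if self.code not in RESPONSE_LABELS:
            raise ValueError(f"invalid response code {self.code!r}")
        if self.label != RESPONSE_LABELS[self.code]:
            raise ValueError(f"label {self.label!r} inconsistent with code {self.code!r}")


def bound_gene_set(assignments: Sequence[PeakGeneAssignment]) -> set[str]:
    """Unique gene ids with at least one allocated peak."""
    return {a.gene_id for a in assignments if a.gene_id is not None}


def direct_target_split(
    degs: Mapping[str, set[str]], bound: set[str]
) -> pd.DataFrame:
    """Per-direction split of differentially expressed genes by binding.

    ``degs`` maps direction label (e.g. 'up', 'down') to gene sets.
    Returns one row per direction: counts of bound/unbound DEGs and the
    bound ('direct target') fraction, plus a 'bound_total' row reporting
    the fraction of bound genes that are DEGs anywhere.
    """
    rows = []
    all_degs: set[str] = set()
    for direction, genes in degs.items():
        all_degs |= genes
        n_bound = len(genes & bound)
        n = len(genes)
        rows.append(
            {
                "direction": direction,
                "n_deg": n,
                "n_bound": n_bound,
                "n_unbound": n - n_bound,
                "fraction_bound": n_bound / n if n else float("nan"),
            }
        )
    rows.append(
        {
            "direction": "bound_total",
            "n_deg": len(all_degs & bound),
            "n_bound": len(bound),
            "n_unbound": len(bound - all_degs),
            "fraction_bound": len(all_degs & bound) / len(bound) if bound else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def classify_response(
    codes_uninduced: Sequence[PatternCode],
    codes_induced: Sequence[PatternCode],
    bound: set[str] | None = None,
    digit_index: int = 0,
    include_unresponsive: bool = False,
) -> list[ResponseClass]:
    """Two-digit response classes for (by default) bound genes.

    The class code concatenates a gene's uninduced digit and induced digit
    for the chosen comparison (``digit_index``).  Both code tables must
    cover exactly the same genes.  The all-invariant class '22' is dropped
    from the default report ("eight classes"); pass
    ``include_unresponsive=True`` for the full nine-class census.
    """
    uninduced = {c.gene_id: c.code for c in codes_uninduced}
    induced = {c.gene_id: c.code for c in codes_induced}
    if set(uninduced) != set(induced):
        only = set(uninduced) ^ set(induced)
        raise ValueError(f"gene(s) present in only one code table: {sorted(only)[:5]}")
    out = []
    for gene_id in sorted(uninduced):
        if bound is not None and gene_id not in bound:
            continue
        code = uninduced[gene_id][digit_index] + induced[gene_id][digit_index]
        if code == "22" and not include_unresponsive:
            continue
        out.append(ResponseClass(gene_id, code, RESPONSE_LABELS[code]))
    return out


def response_census(classes: Sequence[ResponseClass]) -> pd.DataFrame:
    """Class-count summary keyed by both code and label."""
    rows = []
    for code in sorted(RESPONSE_LABELS):
        n = sum(1 for c in classes if c.code == code)
        rows.append({"code": code, "label": RESPONSE_LABELS[code], "n": n})
    return pd.DataFrame(rows)
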