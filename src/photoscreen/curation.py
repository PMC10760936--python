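"""Post-screen hit-list curation with a full audit trail.

After statistical hit calling, a screened gene list is refined by
documented, data-driven edits: removing genes whose insertion mapping could
not be validated, genes co-occurring with an established photosynthesis gene
in the same strain, dual-hit strains collapsed to one retained gene, and
genes whose expression is unaffected in the mutant; and adding back genes
validated despite low mapping confidence or reinstated after manual review
of a faulty replicate.  Every change carries a reason code and provenance
note, and replaying the ledger reproduces the final list exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["REMOVAL_REASONS", "ADDITION_REASONS", "CurationLedger", "apply_curation"]

REMOVAL_REASONS = (
    "mapping-unvalidated",
    "co-occurring-with-established",
    "dual-hit-collapsed",
    "expression-unaffected",
)

ADDITION_REASONS = (
    "confidence4-validated",
    "manual-reinstated",
)


@dataclass
class CurationLedger:
    """Auditable record of a curation pass."""

    start: list[str]
    events: pd.DataFrame  # columns: action, gene, reason, note
    final: list[str]

    def reconciles(self) -> bool:
        """Check |final| = |start| - removals + additions."""
        n_rm = int((self.events["action"] == "remove").sum())
        n_add = int((self.events["action"] == "add").sum())
        return len(self.final) == len(self.start) - n_rm + n_add

    def replay(self) -> list[str]:
        """Re-derive the final list from start + events."""
        current = list(self.start)
        for _, ev in self.events.iterrows():
            if ev["action"] == "remove":
                current.remove(ev["gene"])
            else:
                current.append(ev["gene"])
        return sorted(current)


def apply_curation(
    start: list[str],
    removals: pd.DataFrame | None = None,
    additions: pd.DataFrame | None = None,
) -> CurationLedger:
    """Apply removal and addition tables to a starting gene list.

    Both tables need ``gene`` and ``reason`` columns (``note`` optional).
    Removals are applied first, then additions; removing an absent gene or
    adding an already-present gene is an error.  Re-adding a gene removed
    earlier in the same pass is allowed and leaves both events in the
    ledger.
    """
    empty = pd.DataFrame(columns=["gene", "reason", "note"])
    removals = removals if removals is not None else empty
    additions = additions if additions is not None else empty
    for tbl, name in ((removals, "removals"), (additions, "additions")):
        for col in ("gene", "reason"):
            if col not in tbl.columns:
                raise ValueError(f"{name} table missing column {col!r}")

    current = list(start)
    events = []
    for _, row in removals.iterrows():
        gene = row["gene"]
        if gene not in current:
            raise ValueError(f"cannot remove {gene!r}: not in list")
        current.remove(gene)
        events.append({"action": "remove", "gene": gene, "reason": row["reason"],
                       "note": row.get("note", "")})
    for _, row in additions.iterrows():
        gene = row["gene"]
        if gene in current:
            raise ValueError(f"cannot add {gene!r}: already in list")
        current.append(gene)
        events.append({"action": "add", "gene": gene, "reason": row["reason"],
                       "note": row.get("note", "")})
    ledger = CurationLedger(
        start=list(start),
        events=pd.DataFrame(events, columns=["action", "gene", "reason", "note"]),
        final=sorted(current),
    )
    assert ledger.reconciles()
    return ledger
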