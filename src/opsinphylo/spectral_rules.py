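"""Spectral-tuning classification for the SWS1 (OPN1sw1) conopsin.

Two field rules are implemented over bovine-rhodopsin site numbering:

* Site 86 diagnoses the violet-sensitive (VS) versus ultraviolet-sensitive
  (UVS) pigment class: phenylalanine (F) implies UVS — except in primates,
  where the rule is known to fail and the record is left unclassified —
  while Y, S, V, C or L imply VS. Other residues are unclassified and
  species whose SWS1 copy is inactive are excluded.
* Site 93 residues segregate with activity pattern; the observed
  residue-by-activity contingency table is reported, together with an
  optional concordance score against the field association
  ({T, S, A, M} with nocturnal; {P, V, C} with diurnal) rather than a
  hard-coded classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .phylo_core import TraitTable, ValidationError

UVS_RESIDUES = frozenset("F")
VS_RESIDUES = frozenset("YSVCL")
NOCTURNAL_SITE93 = frozenset("TSAM")
DIURNAL_SITE93 = frozenset("PVC")

GAP_CHARS = frozenset("-.")


@dataclass
class SiteMap:
    """Alignment column (0-based) -> reference position (1-based)."""

    mapping: dict[int, int]
    reference_id: str

    def position_of_column(self, column: int) -> int | None:
        return self.mapping.get(column)

    def column_of_position(self, position: int) -> int | None:
        for col, pos in self.mapping.items():
            if pos == position:
                return col
        return None


def build_site_map(aligned_sequences: dict[str, str], reference_id: str) -> SiteMap:
    """Map alignment columns to reference numbering.

    Column i maps to the count of non-gap reference characters up to and
    including i; gap columns of the reference are unmapped.
    """
    if reference_id not in aligned_sequences:
        raise ValidationError(f"reference {reference_id!r} absent from alignment")
    ref = aligned_sequences[reference_id]
    mapping = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[col] = pos
    return SiteMap(mapping, reference_id)


def residue_at_position(aligned_sequences: dict[str, str], site_map: SiteMap,
                        position: int) -> dict[str, str | None]:
    """Residue of every sequence at a mapped reference position (None when
    the column holds a gap)."""
    col = site_map.column_of_position(position)
    if col is None:
        raise ValidationError(f"reference position {position} is not mapped")
    out = {}
    for sid, seq in aligned_sequences.items():
        ch = seq[col]
        out[sid] = None if ch in GAP_CHARS else ch
    return out


def classify_vs_uvs(site86_residue: str | None, is_primate: bool,
                    sws1_active: bool) -> str:
    """Classify one record as UVS / VS / unclassified / excluded.

    Pure function of (residue, primate flag, active flag): inactive copies
    are excluded; primates with 86F are unclassified (the F rule fails in
    primates and no replacement rule exists); F is UVS; Y/S/V/C/L are VS;
    anything else (including a missing residue) is unclassified.
    """
    if sws1_active is not None and not sws1_active:
        return "excluded"
    if site86_residue is None or (isinstance(site86_residue, float)):
        return "unclassified"
    residue = str(site86_residue).strip().upper()
    if residue in UVS_RESIDUES:
        return "unclassified" if is_primate else "UVS"
    if residue in VS_RESIDUES:
        return "VS"
    return "unclassified"


def classify_trait_table(table: TraitTable) -> pd.DataFrame:
    """Append a ``vs_uvs`` classification column to the trait records."""
    df = table.data.copy()
    df["vs_uvs"] = [
        classify_vs_uvs(row.site86_residue,
                        bool(row.is_primate) if row.is_primate is not None else False,
                        row.sws1_active if row.sws1_active is not None else True)
        for row in df.itertuples()
    ]
    return df


def site93_segregation(table: TraitTable, order_column: str | None = None):
    """Residue-by-activity contingency of site 93.

    Records with a site-93 residue and a nocturnal or diurnal activity are
    counted; cathemeral and unknown records are excluded from the two-column
    table but reported separately. Returns ``(table, excluded_counts)`` or,
    with ``order_column`` present in the data, a third per-order breakdown
    frame.
    """
    df = table.data
    has_residue = df["site93_residue"].notna() & (df["site93_residue"].astype(str) != "")
    df = df[has_residue].copy()
    df["site93_residue"] = df["site93_residue"].astype(str).str.upper()
    in_scope = df["activity_pattern"].isin(["nocturnal", "diurnal"])
    excluded = df.loc[~in_scope, "activity_pattern"].value_counts()
    counted = df[in_scope]
    if counted.empty:
        contingency = pd.DataFrame(columns=["nocturnal", "diurnal"], dtype=int)
    else:
        contingency = (
            counted.groupby(["site93_residue", "activity_pattern"]).size()
            .unstack(fill_value=0)
            .reindex(columns=["nocturnal", "diurnal"], fill_value=0)
        )
        contingency.index.name = "residue"
    if order_column is not None and order_column in table.data.columns:
        breakdown = (
            counted.groupby([order_column, "site93_residue", "activity_pattern"])
            .size().rename("count").reset_index()
        )
        return contingency, excluded, breakdown
    return contingency, excluded


def site93_concordance(contingency: pd.DataFrame) -> float:
    """Fraction of counted records whose residue lies in the activity-matched
    association set (nocturnal: T/S/A/M; diurnal: P/V/C)."""
    total = contingency.to_numpy().sum()
    if total == 0:
        raise ValidationError("empty contingency table")
    hits = 0
    for residue, row in contingency.iterrows():
        if residue in NOCTURNAL_SITE93:
            hits += row.get("nocturnal", 0)
        if residue in DIURNAL_SITE93:
            hits += row.get("diurnal", 0)
    return hits / total
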