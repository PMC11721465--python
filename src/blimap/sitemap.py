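"""Variant-panel binding-site assignment.

Joins a mutagenesis panel (variant name, per-ligand K_D or binding class)
with fold changes versus WT, grades the strongest effect seen at each
structural site (ablating > severe > moderate > neutral, with enhancement
tracked separately), and emits a ligands × sites verdict matrix with a
primary-site call per ligand.

Disease-risk variants are carried through the records but never determine
a primary site on their own: they are graded on a separate axis.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import BlimapError, FormatError
from .kinetics import BindingClass, Direction, FoldChange, fold_change

SITES = ("hydrophobic", "basic", "basic_adjacent", "site2")

#: Structural site of each mutated residue in the bundled receptor panel.
SITE_BY_RESIDUE: dict[int, str] = {
    41: "hydrophobic",
    44: "hydrophobic",
    69: "hydrophobic",
    70: "hydrophobic",
    71: "hydrophobic",
    74: "hydrophobic",
    89: "hydrophobic",
    46: "basic",
    47: "basic",
    62: "basic",
    76: "basic",
    77: "basic",
    87: "basic",
    75: "basic_adjacent",
    78: "basic_adjacent",
    85: "basic_adjacent",
    96: "basic_adjacent",
    122: "site2",
    123: "site2",
}

#: Disease-risk variants: graded, but excluded from site verdicts.
AD_RISK_VARIANTS = frozenset({"R47H", "R62H", "D87N", "T96K"})

#: Default grading thresholds on the affinity fold change.
SEVERE_FOLD = 10.0
MODERATE_FOLD = 2.0

_MUTATION_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


class Verdict(enum.Enum):
    ABLATING = "ablating"
    SEVERE = "severe"
    MODERATE = "moderate"
    ENHANCING = "enhancing"
    NEUTRAL = "neutral"


#: Strength order used to pick per-site verdicts and primary sites.
_RANK = {
    Verdict.ABLATING: 4,
    Verdict.SEVERE: 3,
    Verdict.MODERATE: 2,
    Verdict.ENHANCING: 1,
    Verdict.NEUTRAL: 0,
}


def parse_variant(name: str) -> list[tuple[str, int, str]]:
    """Parse 'L69D/L71D'-style names into (wt_aa, position, mut_aa) triples."""
    name = name.strip()
    if name.upper() == "WT":
        return []
    triples = []
    for token in name.split("/"):
        m = _MUTATION_RE.match(token.strip())
        if not m:
            raise FormatError(f"unparsable variant token {token!r} in {name!r}")
        triples.append((m.group(1), int(m.group(2)), m.group(3)))
    return triples


def variant_site(residues: list[int], site_map: dict[int, str] | None = None) -> str | None:
    """Site label shared by all mutated residues (None for WT).

    A variant spanning several sites takes the label of its strongest-order
    site (hydrophobic > basic > basic_adjacent > site2).
    """
    if not residues:
        return None
    site_map = SITE_BY_RESIDUE if site_map is None else site_map
    labels = set()
    for pos in residues:
        if pos not in site_map:
            raise BlimapError(f"residue {pos} has no site assignment")
        labels.add(site_map[pos])
    for site in SITES:
        if site in labels:
            return site
    return labels.pop()


@dataclass
class VariantRecord:
    name: str
    residues: list[int]
    site: str | None
    is_ad_risk: bool
    ligand: str
    kd: float | None  # M
    binding_class: BindingClass
    fold: FoldChange | None  # None for WT and for unfit/no-binding variants


_CLASS_ALIASES = {
    "binding": BindingClass.BINDING,
    "binding (not fit)": BindingClass.BINDING,
    "decreased binding": BindingClass.DECREASED_BINDING,
    "decreased_binding": BindingClass.DECREASED_BINDING,
    "no binding": BindingClass.NO_BINDING_DETECTED,
    "no binding detected": BindingClass.NO_BINDING_DETECTED,
    "no_binding_detected": BindingClass.NO_BINDING_DETECTED,
    "n.b.d.": BindingClass.NO_BINDING_DETECTED,
    "n.b.d": BindingClass.NO_BINDING_DETECTED,
    "nbd": BindingClass.NO_BINDING_DETECTED,
}

_KD_UNIT_TO_M = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def build_panel(table: pd.DataFrame, site_map: dict[int, str] | None = None) -> list[VariantRecord]:
    """Join a panel table into variant records with folds versus WT.

    Expects columns ``variant, ligand, KD, KD_unit, class`` (KD may be blank
    for qualitative rows).  Each ligand group must contain a WT row with a
    measured K_D, or — for purely qualitative panels — a WT row classed as
    binding.
    """
    for col in ("variant", "ligand", "class"):
        if col not in table.columns:
            raise FormatError(f"panel table missing column {col!r}")

    records: list[VariantRecord] = []
    for ligand, group in table.groupby("ligand", sort=False):
        wt_rows = group[group["variant"].str.strip().str.upper() == "WT"]
        if wt_rows.empty:
            raise BlimapError(f"no WT reference row for ligand {ligand!r}")
        wt_kd = _row_kd(wt_rows.iloc[0])
        for _, row in group.iterrows():
            name = str(row["variant"]).strip()
            triples = parse_variant(name)
            residues = [pos for _, pos, _ in triples]
            kd = _row_kd(row)
            cls = _row_class(row)
            if name.upper() == "WT":
                fold = FoldChange(1.0, Direction.NONE)
            elif kd is not None and wt_kd is not None:
                fold = fold_change(kd, wt_kd)
            else:
                fold = None
            records.append(
                VariantRecord(
                    name=name,
                    residues=residues,
                    site=variant_site(residues, site_map),
                    is_ad_risk=name in AD_RISK_VARIANTS,
                    ligand=str(ligand),
                    kd=kd,
                    binding_class=cls,
                    fold=fold,
                )
            )
    return records


def _row_kd(row) -> float | None:
    if "KD" not in row or pd.isna(row["KD"]) or str(row["KD"]).strip() == "":
        return None
    unit = str(row.get("KD_unit", "M")).strip()
    if unit not in _KD_UNIT_TO_M:
        raise FormatError(f"unknown KD unit {unit!r}")
    return float(row["KD"]) * _KD_UNIT_TO_M[unit]


def _row_class(row) -> BindingClass:
    raw = str(row["class"]).strip().lower()
    if raw not in _CLASS_ALIASES:
        raise FormatError(f"unknown binding class {row['class']!r}")
    return _CLASS_ALIASES[raw]


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def grade_variant(
    record: VariantRecord,
    severe_fold: float = SEVERE_FOLD,
    moderate_fold: float = MODERATE_FOLD,
) -> Verdict:
    """Grade one variant's effect on one ligand.

    No detectable binding is ablating; qualitative decreased binding grades
    moderate; measured affinity decreases grade by fold thresholds.  Affinity
    increases grade enhancing only at the severe threshold — smaller
    increases are treated as neutral for site calling.
    """
    if record.binding_class is BindingClass.NO_BINDING_DETECTED:
        return Verdict.ABLATING
    if record.binding_class is BindingClass.DECREASED_BINDING:
        return Verdict.MODERATE
    if record.fold is None:
        return Verdict.NEUTRAL
    if record.fold.direction is Direction.DECREASE:
        if record.fold.ratio >= severe_fold:
            return Verdict.SEVERE
        if record.fold.ratio >= moderate_fold:
            return Verdict.MODERATE
        return Verdict.NEUTRAL
    if record.fold.direction is Direction.INCREASE and record.fold.ratio >= severe_fold:
        return Verdict.ENHANCING
    return Verdict.NEUTRAL


@dataclass
class SiteCall:
    ligand: str
    verdicts: dict[str, Verdict]  # site -> strongest verdict
    primary: str | None
    secondary: str | None
    ad_risk_verdicts: dict[str, Verdict]  # variant -> verdict (separate axis)


def call_sites(
    panel: list[VariantRecord],
    ligand: str,
    severe_fold: float = SEVERE_FOLD,
    moderate_fold: float = MODERATE_FOLD,
) -> SiteCall:
    """Per-site verdicts and primary/secondary site for one ligand.

    The primary site is the one with the strongest loss-of-binding verdict
    (at least moderate); enhancement and neutral results never define a
    primary site.  Ties break on the canonical site order.
    """
    records = [r for r in panel if r.ligand == ligand and r.site is not None]
    if not records:
        raise BlimapError(f"panel has no variant records for ligand {ligand!r}")
    if len({r.site for r in records if not r.is_ad_risk}) < 2:
        raise BlimapError(f"panel covers fewer than 2 sites for ligand {ligand!r}")

    verdicts = {site: Verdict.NEUTRAL for site in SITES}
    ad_risk = {}
    for rec in records:
        verdict = grade_variant(rec, severe_fold, moderate_fold)
        if rec.is_ad_risk:
            ad_risk[rec.name] = verdict
            continue
        if _RANK[verdict] > _RANK[verdicts[rec.site]]:
            verdicts[rec.site] = verdict

    loss_sites = [
        site
        for site in SITES
        if verdicts[site] in (Verdict.ABLATING, Verdict.SEVERE, Verdict.MODERATE)
    ]
    loss_sites.sort(key=lambda s: (-_RANK[verdicts[s]], SITES.index(s)))
    primary = loss_sites[0] if loss_sites else None
    secondary = loss_sites[1] if len(loss_sites) > 1 else None
    return SiteCall(
        ligand=ligand,
        verdicts=verdicts,
        primary=primary,
        secondary=secondary,
        ad_risk_verdicts=ad_risk,
    )


def ligand_site_matrix(calls: list[SiteCall]) -> pd.DataFrame:
    """Ligands × sites verdict matrix with primary/secondary columns."""
    if not calls:
        raise BlimapError("no site calls supplied")
    rows = []
    for call in calls:
        row = {"ligand": call.ligand}
        row.update({site: call.verdicts[site].value for site in SITES})
        row["primary_site"] = call.primary or "none"
        row["secondary_site"] = call.secondary or "none"
        rows.append(row)
    return pd.DataFrame(rows).set_index("ligand")


# ---------------------------------------------------------------------------
# Bundled panel fixtures
# ---------------------------------------------------------------------------

def load_bundled_panel(name: str) -> pd.DataFrame:
    """Load one of the bundled variant-panel tables (``apoe4``, ``c1q``,
    ``il34``, ``tdp43``)."""
    path = resources.files("blimap.data") / f"panel_{name}.tsv"
    try:
        with resources.as_file(path) as p:
            return pd.read_csv(p, sep="\t")
    except FileNotFoundError:
        raise BlimapError(f"no bundled panel named {name!r}") from None


def load_all_bundled_panels() -> pd.DataFrame:
    """Concatenate all four bundled ligand panels into one table."""
    return pd.concat(
        [load_bundled_panel(n) for n in ("apoe4", "tdp43", "c1q", "il34")],
        ignore_index=True,
    )


def site_report(calls: list[SiteCall]) -> str:
    """Human-readable per-ligand summary."""
    lines = []
    for call in calls:
        lines.append(f"{call.ligand}:")
        lines.append(f"  primary site:   {call.primary or 'none'}")
        lines.append(f"  secondary site: {call.secondary or 'none'}")
        for site in SITES:
            lines.append(f"  {site:<15} {call.verdicts[site].value}")
        if call.ad_risk_verdicts:
            graded = ", ".join(f"{k}={v.value}" for k, v in sorted(call.ad_risk_verdicts.items()))
            lines.append(f"  disease-risk variants (separate axis): {graded}")
        lines.append("")
    return "\n".join(lines)
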