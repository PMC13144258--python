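"""Phenotype coding from replicated herbicide trials.

Each genotype is exposed to a single 4X-label-rate dose of each herbicide in
up to three replicate plants.  Plants are scored for survival and reproduction
three weeks after exposure; non-reproductive plants are re-scored three weeks
later for active growth and reproduction.  A line is *resistant* to a
herbicide if any replicate reproduced (at either timepoint) or displayed
active growth at six weeks; it *reproduced* if any replicate set seed.  These
two stringencies — seed set versus mere survival/regrowth — are both reported
throughout, since they answer different questions (transmission of resistance
versus escape from control).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Herbicide",
    "HERBICIDES",
    "TrialRecord",
    "ResistanceCall",
    "code_resistance",
    "prevalence_table",
    "multi_class_summary",
    "read_trial_table",
    "read_metadata_table",
    "load_bundled_panel_composition",
]

logger = logging.getLogger(__name__)

REGIONS = ("USA", "Canada", "East Asia", "South Asia", "Middle East", "Europe")
OTHER_REGION = "other"


@dataclass(frozen=True)
class Herbicide:
    name: str
    hrac_group: int          # mode-of-action class: 1, 2, 9 or 10
    dose_g_ai_ha: float      # applied dose at 4X the label rate


#: The five screened herbicides with their HRAC class and 4X dose (g ai/ha).
HERBICIDES: tuple[Herbicide, ...] = (
    Herbicide("fluazifop-butyl", 1, 840.0),
    Herbicide("sethoxydim", 1, 840.0),
    Herbicide("nicosulfuron", 2, 136.0),
    Herbicide("glyphosate", 9, 1650.0),
    Herbicide("glufosinate-ammonium", 10, 1936.0),
)

HERBICIDE_BY_NAME: dict[str, Herbicide] = {h.name: h for h in HERBICIDES}


@dataclass(frozen=True)
class TrialRecord:
    """One replicate plant in one herbicide trial."""

    genotype_id: str
    herbicide: str
    replicate: int
    survived_3wk: bool
    reproduced_3wk: bool
    active_growth_6wk: bool
    reproduced_6wk: bool
    treated: bool = True     # False for water-misted controls

    def __post_init__(self) -> None:
        if self.reproduced_3wk and not self.survived_3wk:
            raise ValueError(
                f"{self.genotype_id}/{self.herbicide} rep {self.replicate}: "
                "reproduced at 3 wk but not scored as surviving"
            )
        if self.reproduced_6wk and not (self.active_growth_6wk or self.survived_3wk):
            raise ValueError(
                f"{self.genotype_id}/{self.herbicide} rep {self.replicate}: "
                "reproduced at 6 wk without recorded growth or survival"
            )

    @property
    def reproduced(self) -> bool:
        return self.reproduced_3wk or self.reproduced_6wk


@dataclass(frozen=True)
class ResistanceCall:
    genotype_id: str
    herbicide: str
    resistant: bool          # any replicate reproduced or grew at 6 wk
    reproduced: bool         # any replicate set seed
    survived_3wk: bool       # any replicate alive at 3 wk (looser stringency)

    def __post_init__(self) -> None:
        if self.reproduced and not self.resistant:
            raise ValueError("a reproducing line is by definition resistant")


def code_resistance(records: Iterable[TrialRecord]) -> list[ResistanceCall]:
    """Collapse replicate plants into one resistance call per genotype x herbicide.

    Control (untreated) rows are ignored.  Fewer than three replicates is
    tolerated with a logged warning (trial attrition); conflicting duplicate
    replicate rows raise.
    """
    groups: dict[tuple[str, str], dict[int, TrialRecord]] = defaultdict(dict)
    for rec in records:
        if not rec.treated:
            continue
        key = (rec.genotype_id, rec.herbicide)
        prev = groups[key].get(rec.replicate)
        if prev is not None and prev != rec:
            raise ValueError(
                f"conflicting duplicate rows for {rec.genotype_id}/{rec.herbicide} "
                f"replicate {rec.replicate}"
            )
        groups[key][rec.replicate] = rec
    calls = []
    for (gid, herb), reps in sorted(groups.items()):
        if len(reps) > 3:
            raise ValueError(f"{gid}/{herb}: more than 3 replicates")
        if len(reps) < 3:
            logger.warning("%s/%s: only %d replicate(s) scored", gid, herb, len(reps))
        rs = list(reps.values())
        reproduced = any(r.reproduced for r in rs)
        resistant = reproduced or any(r.active_growth_6wk for r in rs)
        survived = any(r.survived_3wk for r in rs)
        calls.append(ResistanceCall(gid, herb, resistant, reproduced, survived))
    return calls


def prevalence_table(
    calls: Sequence[ResistanceCall],
    regions: Mapping[str, str],
    herbicides: Sequence[Herbicide] = HERBICIDES,
) -> pd.DataFrame:
    """Per-region resistance frequencies at two stringencies.

    Returns a tidy frame with one row per (stringency, region): percentage of
    lines resistant per herbicide, percentage resistant to >= 1 herbicide, and
    the region's line count.  Stringencies: ``reproduction`` (any replicate
    set seed) and ``survival_3wk`` (any replicate alive at 3 weeks).  Unknown
    region labels are bucketed as "other" with a warning.
    """
    by_geno: dict[str, dict[str, ResistanceCall]] = defaultdict(dict)
    for c in calls:
        by_geno[c.genotype_id][c.herbicide] = c
    rows = []
    region_of: dict[str, str] = {}
    for gid in by_geno:
        reg = regions.get(gid)
        if reg is None:
            raise KeyError(f"no region of origin recorded for genotype {gid}")
        if reg not in REGIONS:
            warnings.warn(f"unknown region {reg!r} for {gid}; bucketed as 'other'")
            reg = OTHER_REGION
        region_of[gid] = reg
    herb_names = [h.name for h in herbicides]
    stringency_attr = {"reproduction": "reproduced", "survival_3wk": "survived_3wk"}
    present_regions = [r for r in (*REGIONS, OTHER_REGION)
                       if any(v == r for v in region_of.values())]
    for stringency, attr in stringency_attr.items():
        for reg in present_regions:
            genos = [g for g, r in region_of.items() if r == reg]
            row: dict[str, object] = {"stringency": stringency, "region": reg,
                                      "n_lines": len(genos)}
            any_count = 0
            for g in genos:
                if any(getattr(c, attr) for c in by_geno[g].values()):
                    any_count += 1
            for herb in herb_names:
                n_res = sum(
                    1 for g in genos
                    if herb in by_geno[g] and getattr(by_geno[g][herb], attr)
                )
                row[herb] = 100.0 * n_res / len(genos) if genos else 0.0
            row["any_herbicide"] = 100.0 * any_count / len(genos) if genos else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def multi_class_summary(
    calls: Sequence[ResistanceCall],
    herbicides: Sequence[Herbicide] = HERBICIDES,
    stringency: str = "resistant",
) -> pd.DataFrame:
    """Count distinct HRAC classes resisted per genotype.

    A class counts once however many of its member herbicides were resisted
    (fluazifop + sethoxydim is a single class).  ``stringency`` picks the
    resistance attribute: ``resistant``, ``reproduced`` or ``survived_3wk``.
    The frame carries one row per genotype plus attributes ``frac_multi``
    (fraction with >= 2 classes) and ``n_multi`` in ``.attrs``.
    """
    group_of = {h.name: h.hrac_group for h in herbicides}
    classes: dict[str, set[int]] = defaultdict(set)
    genos: set[str] = set()
    for c in calls:
        genos.add(c.genotype_id)
        if getattr(c, stringency) and c.herbicide in group_of:
            classes[c.genotype_id].add(group_of[c.herbicide])
    rows = [
        {"genotype_id": g, "n_hrac_classes": len(classes.get(g, ())),
         "hrac_classes": ",".join(map(str, sorted(classes.get(g, ()))))}
        for g in sorted(genos)
    ]
    df = pd.DataFrame(rows)
    n_multi = int((df["n_hrac_classes"] >= 2).sum()) if len(df) else 0
    df.attrs["n_multi"] = n_multi
    df.attrs["frac_multi"] = n_multi / len(df) if len(df) else 0.0
    return df


# ---------------------------------------------------------------------------
# delimited-table readers

_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False, "y": True, "n": False}


def _to_bool(x: object) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s not in _BOOL:
        raise ValueError(f"unrecognized boolean token {x!r}")
    return _BOOL[s]


def read_trial_table(path) -> list[TrialRecord]:
    """Read one-row-per-plant trial records from a TSV/CSV table.

    Required columns: genotype_id, herbicide, replicate, survived_3wk,
    reproduced_3wk, active_growth_6wk, reproduced_6wk.  Optional: treated.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    records = []
    for _, row in df.iterrows():
        records.append(
            TrialRecord(
                genotype_id=str(row["genotype_id"]),
                herbicide=str(row["herbicide"]),
                replicate=int(row["replicate"]),
                survived_3wk=_to_bool(row["survived_3wk"]),
                reproduced_3wk=_to_bool(row["reproduced_3wk"]),
                active_growth_6wk=_to_bool(row["active_growth_6wk"]),
                reproduced_6wk=_to_bool(row["reproduced_6wk"]),
                treated=_to_bool(row["treated"]) if "treated" in df.columns else True,
            )
        )
    return records


def read_metadata_table(path) -> pd.DataFrame:
    """Genotype metadata: id, accession, species, region (lat/lon optional)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"genotype_id": str})
    if "genotype_id" not in df.columns:
        raise ValueError("metadata table needs a genotype_id column")
    return df


def load_bundled_panel_composition() -> pd.DataFrame:
    """Species composition of the emulated panel (species, n_genotypes)."""
    from importlib import resources

    path = resources.files("herbiscan.data").joinpath("panel_composition.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
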