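"""Crosslink table ingestion, filtering, mapping onto assemblies.

Consumes xQuest-style exported result tables (protein1, residue1, protein2,
residue2, ld score, link type). A DSS lysine–lysine crosslink is considered
*satisfied* when the Cα–Cα distance in the assembly is at most 35 Å, the
standard bound for that crosslinker; links above the bound are flagged as
violations but never used to hard-reject fits — in a flexible complex a few
violated links are expected, and the downstream ranking uses the
satisfaction fraction as a soft criterion only. The confidence filter keeps
links with xQuest's linear-discriminant (ld) score of at least 40,
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import AtomicModel

logger = logging.getLogger("stainfit")

#: accepted spellings for each mandatory column, after lowercasing and
#: stripping spaces/underscores
_COLUMN_ALIASES = {
    "protein1": {"protein1", "prot1"},
    "residue1": {"residue1", "res1", "abspos1"},
    "protein2": {"protein2", "prot2"},
    "residue2": {"residue2", "res2", "abspos2"},
    "ld_score": {"ldscore", "ld", "score"},
    "link_type": {"linktype", "type"},
}

LINK_TYPES = ("inter", "intra", "monolink")


@dataclass(frozen=True)
class Crosslink:
    """One crosslink identification (or monolink) from the MS search export."""

    protein1: str
    residue1: int
    protein2: str | None
    residue2: int | None
    ld_score: float
    link_type: str = "inter"

    def __post_init__(self) -> None:
        if self.residue1 < 1 or (self.residue2 is not None and self.residue2 < 1):
            raise ValueError("residue numbers must be >= 1")
        if self.link_type not in LINK_TYPES:
            raise ValueError(f"link_type must be one of {LINK_TYPES}")
        if self.link_type == "monolink" and self.residue2 is not None:
            raise ValueError("monolinks carry one residue only")
        if self.link_type != "monolink" and (self.protein2 is None or self.residue2 is None):
            raise ValueError("distance links need both residues")

    @property
    def is_distance_link(self) -> bool:
        return self.link_type != "monolink"


@dataclass
class XlinkConfig:
    """Confidence / distance thresholds and the protein-to-chain mapping.

    ``chain_map`` maps the protein names of the MS table to one or more
    chain ids of the structure; it is always user-supplied, never guessed.
    """

    ld_min: float = 40.0
    max_distance: float = 35.0
    chain_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.ld_min):
            raise ValueError("ld_min must be finite")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        self.chain_map = {
            k: ([v] if isinstance(v, str) else list(v)) for k, v in self.chain_map.items()
        }


@dataclass
class LinkRecord:
    """Mapping outcome for one crosslink."""

    link: Crosslink
    mappable: bool
    distance: float | None = None
    violated: bool = False
    chains_used: tuple[str, str] | None = None
    reason: str | None = None


@dataclass
class CrosslinkMappingResult:
    """Per-link mapping records plus the totals inequality chain.

    ``n_violated <= n_mapped <= n_pass_filter <= n_input`` always holds.
    """

    records: list[LinkRecord]
    n_input: int
    n_pass_filter: int
    n_mapped: int
    n_violated: int

    def __post_init__(self) -> None:
        if not (self.n_violated <= self.n_mapped <= self.n_pass_filter <= self.n_input):
            raise ValueError("totals inequality chain violated")

    @property
    def satisfaction(self) -> float:
        if self.n_mapped == 0:
            raise ValueError("no mappable links")
        return (self.n_mapped - self.n_violated) / self.n_mapped

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "protein1": r.link.protein1, "res1": r.link.residue1,
                "chain1": r.chains_used[0] if r.chains_used else "",
                "protein2": r.link.protein2 or "", "res2": r.link.residue2 or "",
                "chain2": r.chains_used[1] if r.chains_used else "",
                "ld": r.link.ld_score, "link_type": r.link.link_type,
                "distance": "" if r.distance is None else round(r.distance, 3),
                "mappable": r.mappable, "violated": r.violated,
                "note": r.reason or "",
            })
        return pd.DataFrame(rows)

    def totals(self) -> dict[str, int]:
        return {"n_input": self.n_input, "n_pass_filter": self.n_pass_filter,
                "n_mapped": self.n_mapped, "n_violated": self.n_violated}


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _canon(name: str) -> str:
    return name.strip().lower().replace(" ", "").replace("_", "").replace("-", "")


def _resolve_columns(columns) -> dict[str, str]:
    canon_to_real = {_canon(c): c for c in columns}
    resolved = {}
    for target, aliases in _COLUMN_ALIASES.items():
        hit = next((canon_to_real[a] for a in aliases if a in canon_to_real), None)
        if hit is None and target in ("protein1", "residue1", "ld_score"):
            raise ValueError(f"missing mandatory column: {target}")
        resolved[target] = hit
    return resolved


def read_xlink_table(path) -> list[Crosslink]:
    """Read an xQuest-style crosslink table (TSV or CSV, named columns).

    Rows whose residue fields do not parse are rejected with a row-level
    warning diagnostic; a missing mandatory column raises, naming it.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(df.columns)
    links: list[Crosslink] = []
    for row_no, row in df.iterrows():
        try:
            link_type = "inter"
            if cols["link_type"] is not None and not pd.isna(row[cols["link_type"]]):
                link_type = str(row[cols["link_type"]]).strip().lower()
            res2_raw = row[cols["residue2"]] if cols["residue2"] is not None else None
            prot2_raw = row[cols["protein2"]] if cols["protein2"] is not None else None
            if link_type == "monolink" or (res2_raw is None or pd.isna(res2_raw)):
                link_type = "monolink"
                protein2, residue2 = None, None
            else:
                protein2 = str(prot2_raw)
                residue2 = int(res2_raw)
            links.append(Crosslink(
                protein1=str(row[cols["protein1"]]),
                residue1=int(row[cols["residue1"]]),
                protein2=protein2, residue2=residue2,
                ld_score=float(row[cols["ld_score"]]),
                link_type=link_type,
            ))
        except (ValueError, TypeError) as exc:
            logger.warning("crosslink table %s row %s rejected: %s", path, row_no, exc)
    return links


def write_xlink_table(links: list[Crosslink], path) -> None:
    """Write links in the same dialect ``read_xlink_table`` consumes (TSV)."""
    rows = [{
        "protein1": l.protein1, "residue1": l.residue1,
        "protein2": "" if l.protein2 is None else l.protein2,
        "residue2": "" if l.residue2 is None else l.residue2,
        "ld score": l.ld_score, "link type": l.link_type,
    } for l in links]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and mapping
# ---------------------------------------------------------------------------

def filter_crosslinks(links: list[Crosslink], ld_min: float) -> list[Crosslink]:
    """Keep links with ld score >= ``ld_min`` (inclusive; monolinks included)."""
    return [l for l in links if l.ld_score >= ld_min]


def map_crosslinks(assembly: AtomicModel, links: list[Crosslink],
                   config: XlinkConfig) -> CrosslinkMappingResult:
    """Filter links by ld score and map the survivors onto an assembly.

    A distance link is mappable iff both residues exist in the assembly with
    Cα atoms under the configured chain mapping; when a protein maps to
    several chain copies the minimum Cα–Cα distance over copies is used.
    Links to unknown proteins or missing residues are reported as unmappable,
    never silently dropped. Monolinks pass the filter but carry no distance.
    """
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    passed = filter_crosslinks(links, config.ld_min)
    records: list[LinkRecord] = []
    n_mapped = 0
    n_violated = 0
    for link in passed:
        if not link.is_distance_link:
            records.append(LinkRecord(link=link, mappable=False, reason="monolink"))
            continue
        chains1 = config.chain_map.get(link.protein1)
        chains2 = config.chain_map.get(link.protein2)
        if chains1 is None or chains2 is None:
            missing = link.protein1 if chains1 is None else link.protein2
            records.append(LinkRecord(link=link, mappable=False,
                                      reason=f"protein {missing!r} not in chain_map"))
            continue
        best: tuple[float, str, str] | None = None
        for c1 in chains1:
            p1 = assembly.ca_position(c1, link.residue1)
            if p1 is None:
                continue
            for c2 in chains2:
                p2 = assembly.ca_position(c2, link.residue2)
                if p2 is None:
                    continue
                d = float(np.linalg.norm(p1 - p2))
                if best is None or d < best[0]:
                    best = (d, c1, c2)
        if best is None:
            records.append(LinkRecord(link=link, mappable=False,
                                      reason="residue without CA in assembly"))
            continue
        d, c1, c2 = best
        violated = d > config.max_distance
        n_mapped += 1
        n_violated += int(violated)
        records.append(LinkRecord(link=link, mappable=True, distance=d,
                                  violated=violated, chains_used=(c1, c2)))
    return CrosslinkMappingResult(
        records=records, n_input=len(links), n_pass_filter=len(passed),
        n_mapped=n_mapped, n_violated=n_violated,
    )


def satisfaction_fraction(assembly: AtomicModel, links: list[Crosslink],
                          config: XlinkConfig) -> float:
    """Fraction of mapped links within the distance bound."""
    return map_crosslinks(assembly, links, config).satisfaction
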