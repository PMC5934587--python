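"""Market-composition tallies and conservation-status reporting.

Once market samples are identified to species, two summaries matter for
forensics and policy: what fraction of the market each species represents,
and how many of the species are red-listed — globally (IUCN), nationally,
or regionally. "Threatened" is the union of the CR, EN and VU categories;
DD (data deficient), NE (not evaluated) and absent listings never count as
threatened, although the species still count in denominators.

A packaged fixture encodes the status table of the Southern Brazil "cação"
market survey that motivates this package, for use as both an example and
a regression anchor.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "CATEGORIES",
    "THREATENED",
    "ConservationStatusTable",
    "CompositionReport",
    "composition",
    "threat_fractions",
    "load_status_fixture",
    "load_assignment_fixture",
    "load_group_fixture",
]

CATEGORIES = {"CR", "EN", "VU", "NT", "LC", "DD", "NE", "absent"}
THREATENED = {"CR", "EN", "VU"}

_SCOPES = ("global", "national", "regional_1", "regional_2")


@dataclass
class ConservationStatusTable:
    """species -> threat category per jurisdiction."""

    rows: dict  # species -> {scope: category}

    def __post_init__(self):
        for sp, scopes in self.rows.items():
            for scope, cat in scopes.items():
                if scope not in _SCOPES:
                    raise ValueError(f"unknown jurisdiction {scope!r}")
                if cat not in CATEGORIES:
                    raise ValueError(f"{sp}: unknown category {cat!r}")

    @classmethod
    def from_csv(cls, path_or_file) -> "ConservationStatusTable":
        """Load a CSV with columns species, common_name, status_global,
        status_national, status_regional_1, status_regional_2."""
        close = False
        if hasattr(path_or_file, "read"):
            fh = path_or_file
        else:
            fh = open(path_or_file, newline="")
            close = True
        try:
            rows = {}
            for rec in csv.DictReader(fh):
                sp = rec["species"].strip()
                if sp in rows:
                    raise ValueError(f"duplicate species {sp!r}")
                rows[sp] = {
                    "global": rec.get("status_global", "absent") or "absent",
                    "national": rec.get("status_national", "absent") or "absent",
                    "regional_1": rec.get("status_regional_1", "absent") or "absent",
                    "regional_2": rec.get("status_regional_2", "absent") or "absent",
                }
            return cls(rows)
        finally:
            if close:
                fh.close()

    def status(self, species: str, scope: str) -> str:
        return self.rows.get(species, {}).get(scope, "absent")


@dataclass
class CompositionReport:
    """Counts and percentages of identified species in a sample batch."""

    counts: dict
    n_samples: int
    group_counts: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.counts)

    @property
    def percentages(self) -> dict:
        return {sp: round(100.0 * c / self.n_samples, 1)
                for sp, c in self.counts.items()}

    def most_common(self, k: int = 5) -> list:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def composition(assignments, group_map: dict | None = None) -> CompositionReport:
    """Tally assigned species over a batch of identifications.

    ``assignments`` may be AssignmentResult objects or plain
    (sample_id, species) mappings/rows with a ``candidate_species`` key.
    Percentages are reported to one decimal. ``group_map`` (species ->
    group, e.g. taxonomic order) adds per-group counts.
    """
    if not assignments:
        raise ValueError("no assignments to tally")
    counts: dict = {}
    for a in assignments:
        sp = a.candidate_species if hasattr(a, "candidate_species") else a["candidate_species"]
        counts[sp] = counts.get(sp, 0) + 1
    n = sum(counts.values())
    group_counts: dict = {}
    if group_map:
        for sp, c in counts.items():
            grp = group_map.get(sp)
            if grp is None:
                warnings.warn(f"species {sp!r} missing from group map")
                grp = "unknown"
            group_counts[grp] = group_counts.get(grp, 0) + c
    return CompositionReport(counts=counts, n_samples=n, group_counts=group_counts)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def threat_fractions(species_list, table: ConservationStatusTable,
                     scope: str = "global",
                     category_set=frozenset(THREATENED)) -> int:
    """Percentage of species red-listed in ``category_set`` at ``scope``.

    The denominator is every species in ``species_list`` (deduplicated);
    species absent from the table stay in the denominator but never count
    as threatened. Rounded half-up to an integer percentage.
    """
    species = sorted(set(species_list))
    if not species:
        raise ValueError("species list is empty")
    if scope not in _SCOPES:
        raise ValueError(f"unknown jurisdiction {scope!r}; expected one of {_SCOPES}")
    bad = set(category_set) - CATEGORIES
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    effective = set(category_set) - {"DD", "NE", "absent"}
    missing = [sp for sp in species if sp not in table.rows]
    if missing:
        warnings.warn(f"species not in status table (kept in denominator): {missing}")
    hits = sum(1 for sp in species if table.status(sp, scope) in effective)
    return _round_half_up(100.0 * hits / len(species))


def _fixture(name: str):
    return resources.files("barcodeid.data").joinpath(name)


def load_status_fixture() -> ConservationStatusTable:
    """The packaged conservation-status table of the market survey."""
    with _fixture("market_survey_status.csv").open() as fh:
        return ConservationStatusTable.from_csv(fh)


def load_assignment_fixture() -> list:
    """The packaged 63-sample market identification table (sample, species,
    average distance, top-hit coverage/identity)."""
    with _fixture("market_survey_assignments.tsv").open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_group_fixture() -> dict:
    """species -> taxonomic group (order) map for the market survey."""
    with _fixture("market_survey_groups.tsv").open() as fh:
        return {r["species"]: r["group"] for r in csv.DictReader(fh, delimiter="\t")}
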