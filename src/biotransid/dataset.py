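"""Packaged reference table of neobavaisoflavone and its 72 metabolites.

The resource ``data/metabolites.tsv`` transcribes the published
identification table: per row a metabolite label, retention time, the
deprotonated (or, for the parent's positive-mode entry, protonated) ion
formula, printed theoretical and experimental m/z, RDB, the reaction label
(e.g. ``M+SO3+C6H8O6``), the truncated MS2 fragment list, and a
detected/undetected flag for each of the seven matrices.

Two integrity flags accompany each row, frozen when the table was packaged:

* ``theoretical_anomaly`` — the printed theoretical m/z disagrees with the
  value recomputed from the ion formula by more than 1.5e-5 Da (the printed
  column is internally inconsistent for 20 of 74 rows, up to ~1 Da);
* ``experimental_anomaly`` — the printed experimental m/z implies a mass
  error above 5 ppm, contradicting the table's own error column (11 rows,
  one of them ~6 Da off). For these rows ``experimental_mz`` is
  reconstructed as computed-theoretical x (1 + printed-error-ppm x 1e-6);
  the printed value is retained in ``experimental_mz_printed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

from .formula import ElementalFormula, parse_formula
from .spectra import MATRICES

PARENT_FORMULA = "C20H18O4"  #: neutral formula of neobavaisoflavone


@dataclass(frozen=True)
class FixtureRow:
    """One row of the packaged metabolite table."""

    metabolite_id: str
    adduct: str
    rt: float
    ion_formula: ElementalFormula
    neutral_formula: ElementalFormula
    theoretical_mz_printed: float
    experimental_mz_printed: float
    experimental_mz: float
    rdb: float
    error_ppm_printed: float
    reaction_label: str
    fragments: Tuple[Tuple[float, float], ...]
    presence: Dict[str, bool]
    theoretical_anomaly: bool
    experimental_anomaly: bool

    @property
    def is_parent(self) -> bool:
        return self.metabolite_id.startswith("M0")

    @property
    def polarity(self) -> str:
        return "positive" if self.adduct == "[M+H]+" else "negative"


def _parse_fragments(text: str) -> Tuple[Tuple[float, float], ...]:
    out = []
    for token in text.strip().rstrip(",").split(","):
        token = token.strip()
        if not token:
            continue
        mz, rel = token.rstrip(")").split("(")
        out.append((float(mz), float(rel)))
    return tuple(out)


def load_fixture() -> List[FixtureRow]:
    """Load the packaged table: 72 metabolite rows plus 2 parent-ion rows."""
    text = resources.files("biotransid.data").joinpath("metabolites.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows: List[FixtureRow] = []
    proton = parse_formula("H")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        ion = parse_formula(rec["ion_formula"])
        neutral = ion + proton if rec["adduct"] == "[M-H]-" else ion - proton
        rows.append(
            FixtureRow(
                metabolite_id=rec["id"],
                adduct=rec["adduct"],
                rt=float(rec["rt_min"]),
                ion_formula=ion,
                neutral_formula=neutral,
                theoretical_mz_printed=float(rec["theoretical_mz_printed"]),
                experimental_mz_printed=float(rec["experimental_mz_printed"]),
                experimental_mz=float(rec["experimental_mz"]),
                rdb=float(rec["rdb"]),
                error_ppm_printed=float(rec["error_ppm_printed"]),
                reaction_label=rec["reaction_label"],
                fragments=_parse_fragments(rec["fragments"]),
                presence={m: rec[m] == "+" for m in MATRICES},
                theoretical_anomaly=rec["theoretical_anomaly"] == "1",
                experimental_anomaly=rec["experimental_anomaly"] == "1",
            )
        )
    if len(rows) != 74:
        raise RuntimeError(f"corrupted resource: expected 74 rows, got {len(rows)}")
    return rows


def metabolite_rows(fixture: List[FixtureRow] | None = None) -> List[FixtureRow]:
    """The 72 metabolite rows (parent-ion entries excluded)."""
    fixture = load_fixture() if fixture is None else fixture
    return [r for r in fixture if not r.is_parent]


def parent_rows(fixture: List[FixtureRow] | None = None) -> List[FixtureRow]:
    """The parent compound's negative- and positive-mode entries."""
    fixture = load_fixture() if fixture is None else fixture
    return [r for r in fixture if r.is_parent]
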