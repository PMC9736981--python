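"""Biotransformation reaction library and candidate-metabolite enumeration.

A :class:`Reaction` is a net elemental delta (atoms added, atoms removed)
with a multiplicity bound — e.g. hydroxylation (+O, up to 3 times) or
glucuronidation (+C6H8O6, up to twice). Candidate metabolites are generated
by breadth-first closure of the reaction network over a parent compound's
neutral formula, deduplicated by resulting formula, and screened by an
elemental-composition filter. No structural or site-of-metabolism reasoning
is attempted: isomers share one candidate and are resolved downstream by
retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .formula import (
    CompositionFilter,
    ElementalFormula,
    FormulaError,
    default_composition_filter,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
    rdb,
)


class ReactionLibraryError(ValueError):
    """Bad reaction-library config: duplicate names or unparseable deltas."""


@dataclass(frozen=True)
class Reaction:
    """A biotransformation expressed as formula arithmetic.

    ``add`` and ``remove`` are applied ``multiplicity`` times per step;
    ``phase`` is "I" (functionalization) or "II" (conjugation) and is carried
    as metadata only.
    """

    name: str
    label: str
    add: ElementalFormula
    remove: ElementalFormula
    phase: str
    max_multiplicity: int = 1

    def __post_init__(self):
        if self.max_multiplicity < 1:
            raise ReactionLibraryError(f"{self.name}: max_multiplicity must be >= 1")
        if self.add == self.remove:
            raise ReactionLibraryError(f"{self.name}: net formula delta is zero")

    @property
    def delta_mass(self) -> float:
        """Net monoisotopic mass shift per application (Da, signed)."""
        return monoisotopic_mass(self.add) - monoisotopic_mass(self.remove)


def _parse_delta(text: str) -> ElementalFormula:
    text = text.strip()
    if text in ("", "-", "."):
        return ElementalFormula()
    return parse_formula(text)


def load_reaction_library(path: Optional[str | Path] = None) -> List[Reaction]:
    """Load a tab-separated reaction library.

    Columns: name, label, add-formula, remove-formula, phase,
    max_multiplicity; '-' denotes an empty formula; '#' starts a comment.
    With no ``path`` the packaged default library is returned.
    """
    if path is None:
        text = resources.files("biotransid.data").joinpath("reactions.tsv").read_text()
    else:
        text = Path(path).read_text()
    reactions: List[Reaction] = []
    seen = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ReactionLibraryError(f"line {lineno}: expected 6 tab-separated fields")
        name, label, add, remove, phase, mult = parts
        if name in seen:
            raise ReactionLibraryError(f"line {lineno}: duplicate reaction name {name!r}")
        seen.add(name)
        try:
            reaction = Reaction(
                name=name,
                label=label,
                add=_parse_delta(add),
                remove=_parse_delta(remove),
                phase=phase,
                max_multiplicity=int(mult),
            )
        except (FormulaError, ValueError) as exc:
            raise ReactionLibraryError(f"line {lineno} ({name}): {exc}") from exc
        reactions.append(reaction)
    return reactions


def apply_reaction(formula: ElementalFormula, reaction: Reaction, multiplicity: int = 1) -> ElementalFormula:
    """Apply ``reaction`` ``multiplicity`` times to ``formula``.

    Raises :class:`FormulaError` (naming the element) if any count would go
    negative, and ``ValueError`` if multiplicity exceeds the reaction's bound.
    """
    if not 1 <= multiplicity <= reaction.max_multiplicity:
        raise ValueError(
            f"multiplicity {multiplicity} outside [1, {reaction.max_multiplicity}] "
            f"for reaction {reaction.name!r}"
        )
    return formula + reaction.add * multiplicity - reaction.remove * multiplicity


PathStep = Tuple[Reaction, int]


@dataclass(frozen=True)
class CandidateMetabolite:
    """A reachable product formula with its minimal generating path.

    ``path`` is the step-count-minimal (then lexicographically smallest by
    reaction-name sequence) list of (reaction, multiplicity) pairs producing
    ``formula`` from ``parent``; ``n_steps`` counts multiplicities.
    """

    parent: ElementalFormula
    path: Tuple[PathStep, ...]
    formula: ElementalFormula
    theoretical_mz: Dict[str, float] = field(compare=False, default_factory=dict)
    rdb_ion: float = field(compare=False, default=0.0)

    @property
    def n_steps(self) -> int:
        return sum(mult for _, mult in self.path)

    @property
    def path_label(self) -> str:
        if not self.path:
            return "parent"
        return " + ".join(
            name if mult == 1 else f"{mult}x {name}"
            for name, mult in ((r.name, m) for r, m in self.path)
        )

    def __repr__(self) -> str:
        return f"CandidateMetabolite({self.formula.hill()}, path={self.path_label!r})"


def _path_key(path: Tuple[PathStep, ...]) -> Tuple:
    names = tuple(r.name for r, m in path for _ in range(m))
    return (len(names), names)


def enumerate_candidates(
    parent: ElementalFormula,
    library: Sequence[Reaction],
    max_steps: int = 4,
    comp_filter: Optional[CompositionFilter] = None,
    adducts: Sequence[str] = ("[M-H]-",),
) -> List[CandidateMetabolite]:
    """Closure of the biotransformation network over ``parent``.

    Candidates are the feasible multisets of reaction applications: each
    library reaction applied up to its multiplicity bound, an application at
    multiplicity *n* counting as *n* steps, total steps <= ``max_steps``,
    no element count going negative. One candidate is returned per distinct
    product formula, carrying the minimal path (fewest steps, ties broken by
    the lexicographically smallest reaction-name sequence); the candidate set
    therefore grows monotonically with ``max_steps``. Products failing
    ``comp_filter`` are dropped, except the parent itself (zero steps), which
    is always included. Output is sorted by step count, then Hill formula.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    if comp_filter is None:
        comp_filter = default_composition_filter()

    # The reaction algebra is commutative, so candidates are exactly the
    # feasible multisets of reaction applications: each reaction applied a
    # total of 0..max_multiplicity times, total applications <= max_steps,
    # every element count non-negative in the resulting formula. Per formula
    # the minimal multiset is kept (fewest steps, then the lexicographically
    # smallest reaction-name sequence).
    ordered = sorted(library, key=lambda r: r.name)
    best: Dict[ElementalFormula, Tuple] = {}
    paths: Dict[ElementalFormula, Tuple[PathStep, ...]] = {}

    def record(formula: ElementalFormula, path: Tuple[PathStep, ...]) -> None:
        key = _path_key(path)
        if formula not in best or key < best[formula]:
            best[formula] = key
            paths[formula] = path

    def walk(index: int, steps_left: int, delta_add: ElementalFormula,
             delta_remove: ElementalFormula, path: Tuple[PathStep, ...]) -> None:
        try:
            formula = parent + delta_add - delta_remove
        except FormulaError:
            formula = None
        if formula is not None:
            record(formula, path)
        if index == len(ordered) or steps_left == 0:
            return
        reaction = ordered[index]
        walk(index + 1, steps_left, delta_add, delta_remove, path)
        for mult in range(1, min(reaction.max_multiplicity, steps_left) + 1):
            walk(
                index + 1,
                steps_left - mult,
                delta_add + reaction.add * mult,
                delta_remove + reaction.remove * mult,
                path + ((reaction, mult),),
            )

    empty = ElementalFormula()
    walk(0, max_steps, empty, empty, ())
    record(parent, ())  # the parent is always a candidate

    out: List[CandidateMetabolite] = []
    for formula, path in paths.items():
        if formula != parent and not _passes(formula, comp_filter):
            continue
        mzs = {}
        for adduct in adducts:
            try:
                mzs[adduct] = ion_mz(formula, adduct)
            except FormulaError:
                continue
        anion = formula - parse_formula("H") if formula["H"] else formula
        out.append(
            CandidateMetabolite(
                parent=parent,
                path=path,
                formula=formula,
                theoretical_mz=mzs,
                rdb_ion=rdb(anion),
            )
        )
    out.sort(key=lambda c: (c.n_steps, c.formula.hill()))
    return out


def _passes(formula: ElementalFormula, comp: CompositionFilter) -> bool:
    from .formula import passes_composition_filter

    return passes_composition_filter(formula, comp)
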