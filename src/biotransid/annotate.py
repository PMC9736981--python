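"""Candidate-to-peak annotation with MS2 confirmation.

The engine matches enumerated candidate metabolites to MS1 features within a
ppm window (negative mode for metabolites; positive mode is consulted only
for the parent compound), attaches MS2 evidence — diagnostic product ions
(DPIs) and neutral-loss fragments (NLFs) — assigns a confidence tier, and
consolidates same-formula observations into distinct metabolite records by
retention time (or by carried feature labels), producing the
metabolite-by-matrix presence table.

Confidence tiers are an artifact of this pipeline, not of the source study:
A = two or more MS2 evidence items, B = exactly one, C = MS1 match only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formula import (
    CompositionFilter,
    ElementalFormula,
    default_composition_filter,
    ion_formula_mz,
    parse_formula,
    ppm_error,
)
from .reactions import CandidateMetabolite, Reaction, enumerate_candidates, load_reaction_library
from .spectra import (
    MATRICES,
    PLASMA_MATRICES,
    IntensityThresholds,
    MS2Spectrum,
    Peak,
    filter_by_intensity,
)


# ---------------------------------------------------------------------------
# evidence libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticIon:
    """A class-characteristic MS2 fragment (literal m/z or ion formula)."""

    label: str
    mz: Optional[float] = None
    formula: Optional[ElementalFormula] = None
    tolerance_mode: str = "da"  # "da" or "ppm"
    tolerance: float = 0.01
    context: str = ""

    def __post_init__(self):
        if (self.mz is None) == (self.formula is None):
            raise ValueError(f"{self.label}: exactly one of mz/formula required")
        if self.mz is not None and self.mz <= 0:
            raise ValueError(f"{self.label}: literal m/z must be positive")

    def target_mz(self, polarity: str) -> float:
        if self.mz is not None:
            return self.mz
        return ion_formula_mz(self.formula, -1 if polarity == "negative" else +1)

    def matches(self, fragment_mz: float, polarity: str) -> bool:
        target = self.target_mz(polarity)
        if self.tolerance_mode == "ppm":
            return abs(ppm_error(fragment_mz, target)) <= self.tolerance
        return abs(fragment_mz - target) <= self.tolerance


@dataclass(frozen=True)
class NeutralLoss:
    """A precursor-minus-fragment mass difference (formula or literal Da)."""

    label: str
    delta_formula: Optional[ElementalFormula] = None
    delta_mass: Optional[float] = None
    radical_allowed: bool = False

    def __post_init__(self):
        if (self.delta_formula is None) == (self.delta_mass is None):
            raise ValueError(f"{self.label}: exactly one of formula/mass required")
        if self.mass <= 0:
            raise ValueError(f"{self.label}: loss mass must be positive")

    @property
    def mass(self) -> float:
        if self.delta_mass is not None:
            return self.delta_mass
        from .formula import monoisotopic_mass

        return monoisotopic_mass(self.delta_formula)


def _looks_like_formula(text: str) -> bool:
    return bool(text) and text[0].isalpha()


def load_dpi_library(path: Optional[str | Path] = None) -> List[DiagnosticIon]:
    """Load a DPI library TSV (label, target, mode, tolerance, context)."""
    if path is None:
        text = resources.files("biotransid.data").joinpath("dpi_library.tsv").read_text()
    else:
        text = Path(path).read_text()
    ions = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, target, mode, tol, context = line.split("\t")
        if _looks_like_formula(target):
            ions.append(DiagnosticIon(label, formula=parse_formula(target),
                                      tolerance_mode=mode, tolerance=float(tol),
                                      context=context))
        else:
            ions.append(DiagnosticIon(label, mz=float(target), tolerance_mode=mode,
                                      tolerance=float(tol), context=context))
    return ions


def load_neutral_loss_library(path: Optional[str | Path] = None) -> List[NeutralLoss]:
    """Load an NLF library TSV (label, delta, radical_allowed)."""
    if path is None:
        text = resources.files("biotransid.data").joinpath("neutral_losses.tsv").read_text()
    else:
        text = Path(path).read_text()
    losses = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, delta, radical = line.split("\t")
        if _looks_like_formula(delta):
            losses.append(NeutralLoss(label, delta_formula=parse_formula(delta),
                                      radical_allowed=radical == "1"))
        else:
            losses.append(NeutralLoss(label, delta_mass=float(delta),
                                      radical_allowed=radical == "1"))
    return losses


# ---------------------------------------------------------------------------
# MS1 matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MS1Match:
    """The best candidate for one peak, with in-tolerance alternates."""

    candidate: CandidateMetabolite
    peak: Peak
    ppm: float
    adduct: str
    alternates: Tuple[Tuple[CandidateMetabolite, float], ...] = ()


def match_ms1(
    candidates: Sequence[CandidateMetabolite],
    peaks: Sequence[Peak],
    max_ppm: float = 10.0,
    thresholds: Optional[IntensityThresholds] = None,
    positive_parent_only: bool = True,
) -> List[MS1Match]:
    """Match each peak to the candidate minimising |ppm| within ``max_ppm``.

    Negative-mode peaks are matched against [M-H]- candidate masses; positive
    peaks against [M+H]+ (restricted to the parent when
    ``positive_parent_only``, reflecting that conjugates of this scaffold
    ionise in negative mode). Ties are broken by fewest reaction steps, then
    Hill formula. Alternates within tolerance are retained, sorted the same
    way. Peaks with no candidate in tolerance are omitted.
    """
    if thresholds is not None:
        peaks = filter_by_intensity(peaks, thresholds)

    by_adduct: Dict[str, Tuple[np.ndarray, list]] = {}
    for adduct in ("[M-H]-", "[M+H]+"):
        pool = [
            c for c in candidates
            if adduct in c.theoretical_mz
            and not (adduct == "[M+H]+" and positive_parent_only and c.n_steps > 0)
        ]
        mzs = np.array([c.theoretical_mz[adduct] for c in pool])
        order = np.argsort(mzs)
        by_adduct[adduct] = (mzs[order], [pool[i] for i in order])

    matches: List[MS1Match] = []
    for peak in peaks:
        adduct = "[M-H]-" if peak.polarity == "negative" else "[M+H]+"
        mzs, pool = by_adduct[adduct]
        if len(pool) == 0:
            continue
        half = max_ppm * 1e-6 * peak.mz
        lo = np.searchsorted(mzs, peak.mz - half, side="left")
        hi = np.searchsorted(mzs, peak.mz + half, side="right")
        hits = []
        for i in range(lo, hi):
            err = ppm_error(peak.mz, mzs[i])
            if abs(err) <= max_ppm:
                hits.append((pool[i], err))
        if not hits:
            continue
        hits.sort(key=lambda h: (abs(h[1]), h[0].n_steps, h[0].formula.hill()))
        best, err = hits[0]
        matches.append(
            MS1Match(candidate=best, peak=peak, ppm=err, adduct=adduct,
                     alternates=tuple(hits[1:]))
        )
    return matches


# ---------------------------------------------------------------------------
# MS2 evidence
# ---------------------------------------------------------------------------

def match_dpis(
    spectrum: MS2Spectrum,
    library: Sequence[DiagnosticIon],
    tol_da: Optional[float] = None,
) -> List[Tuple[DiagnosticIon, float]]:
    """One hit per library entry whose target lies within tolerance of some
    fragment; a single fragment may evidence several entries. ``tol_da``
    overrides every entry's own tolerance with an absolute window."""
    hits = []
    for ion in library:
        for frag_mz, _ in spectrum.fragments:
            ok = (
                abs(frag_mz - ion.target_mz(spectrum.polarity)) <= tol_da
                if tol_da is not None
                else ion.matches(frag_mz, spectrum.polarity)
            )
            if ok:
                hits.append((ion, frag_mz))
                break
    return hits


def detect_neutral_losses(
    spectrum: MS2Spectrum,
    precursor_mz: float,
    library: Sequence[NeutralLoss],
    tol_da: float = 0.01,
    include_fragment_pairs: bool = False,
) -> List[Tuple[NeutralLoss, float, float]]:
    """Hits (loss, from_mz, to_mz) where a mass difference matches a library
    delta within ``tol_da``. Differences are taken precursor-to-fragment and,
    when ``include_fragment_pairs``, between fragment pairs (successive
    losses). A zero difference (fragment == precursor) is never a loss."""
    hits = []
    pairs = [(precursor_mz, frag) for frag, _ in spectrum.fragments]
    if include_fragment_pairs:
        frags = sorted(f for f, _ in spectrum.fragments)
        pairs += [(b, a) for i, a in enumerate(frags) for b in frags[i + 1:]]
    for loss in library:
        for src, dst in pairs:
            delta = src - dst
            if delta <= 0.5:
                continue
            if abs(delta - loss.mass) <= tol_da:
                hits.append((loss, src, dst))
                break
    return hits


def assign_confidence(
    match: MS1Match,
    dpi_hits: Sequence = (),
    nl_hits: Sequence = (),
) -> str:
    """Tier A (>=2 MS2 evidence items), B (exactly 1), C (MS1-only)."""
    n = len(dpi_hits) + len(nl_hits)
    return "A" if n >= 2 else ("B" if n == 1 else "C")


def associate_spectra(
    peak: Peak,
    spectra: Sequence[MS2Spectrum],
    precursor_tol_ppm: float = 20.0,
    rt_tol: float = 0.2,
) -> List[MS2Spectrum]:
    """Spectra acquired on this feature: same polarity, precursor within
    ``precursor_tol_ppm`` of the peak m/z, retention time within ``rt_tol``
    minutes."""
    out = []
    for s in spectra:
        if s.polarity != peak.polarity:
            continue
        if abs(ppm_error(s.precursor_mz, peak.mz)) > precursor_tol_ppm:
            continue
        if abs(s.rt - peak.rt) > rt_tol:
            continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# consolidation into metabolite records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchEvidence:
    """One matched peak together with its MS2 evidence."""

    match: MS1Match
    dpi_hits: Tuple[Tuple[DiagnosticIon, float], ...] = ()
    nl_hits: Tuple[Tuple[NeutralLoss, float, float], ...] = ()


@dataclass(frozen=True)
class AnnotatedMetabolite:
    """A distinct metabolite: one formula at one retention-time cluster,
    observed in one or more matrices."""

    metabolite_id: str
    representative: MatchEvidence
    observations: Tuple[MatchEvidence, ...]
    rt: float
    confidence: str
    matrix_presence: Dict[str, bool]

    @property
    def formula(self) -> ElementalFormula:
        return self.representative.match.candidate.formula

    @property
    def candidate(self) -> CandidateMetabolite:
        return self.representative.match.candidate

    @property
    def dpi_hits(self):
        return self.representative.dpi_hits

    @property
    def nl_hits(self):
        return self.representative.nl_hits


def _cluster_by_rt(rts: List[float], tol: float) -> List[List[int]]:
    """Single-linkage 1-D clustering: a gap > tol starts a new cluster."""
    order = sorted(range(len(rts)), key=lambda i: rts[i])
    clusters: List[List[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if rts[cur] - rts[prev] > tol:
            clusters.append([])
        clusters[-1].append(cur)
    return clusters


def consolidate_isomers(
    evidences: Sequence[MatchEvidence],
    rt_tol: float = 0.2,
    use_feature_ids: bool = False,
) -> List[AnnotatedMetabolite]:
    """Group matched peaks into distinct metabolite records.

    Observations sharing a formula are split when their retention times
    differ by more than ``rt_tol`` (isomers) and merged across matrices when
    they do not. With ``use_feature_ids`` the grouping key is the feature
    label carried on the peaks (available for synthetic runs and PRM
    inclusion lists) instead of the RT cluster. The total number of
    observations is preserved — only their grouping changes.
    """
    groups: Dict[Tuple, List[MatchEvidence]] = {}
    if use_feature_ids:
        for ev in evidences:
            key = (ev.match.peak.feature_id,)
            groups.setdefault(key, []).append(ev)
    else:
        by_formula: Dict[str, List[MatchEvidence]] = {}
        for ev in evidences:
            by_formula.setdefault(ev.match.candidate.formula.hill(), []).append(ev)
        for hill, evs in by_formula.items():
            for cluster in _cluster_by_rt([e.match.peak.rt for e in evs], rt_tol):
                key = (hill, min(evs[i].match.peak.rt for i in cluster))
                groups.setdefault(key, []).extend(evs[i] for i in cluster)

    records: List[AnnotatedMetabolite] = []
    for key, evs in groups.items():
        evs = sorted(evs, key=lambda e: abs(e.match.ppm))
        rep = evs[0]
        rt = median(e.match.peak.rt for e in evs)
        presence = {m: False for m in MATRICES}
        dpi_labels, nl_labels = set(), set()
        for e in evs:
            presence[e.match.peak.matrix] = True
            dpi_labels.update(ion.label for ion, _ in e.dpi_hits)
            nl_labels.update(loss.label for loss, _, _ in e.nl_hits)
        n_evidence = len(dpi_labels) + len(nl_labels)
        confidence = "A" if n_evidence >= 2 else ("B" if n_evidence == 1 else "C")
        if use_feature_ids and key[0] is not None:
            mid = str(key[0])
        else:
            mid = f"{rep.match.candidate.formula.hill()}@{rt:.2f}"
        records.append(
            AnnotatedMetabolite(
                metabolite_id=mid,
                representative=rep,
                observations=tuple(evs),
                rt=rt,
                confidence=confidence,
                matrix_presence=presence,
            )
        )
    records.sort(key=lambda r: (r.rt, r.formula.hill()))
    return records


def build_presence_matrix(annotations: Sequence[AnnotatedMetabolite]) -> pd.DataFrame:
    """Boolean metabolite x matrix table (rows ordered as the input)."""
    data = {m: [a.matrix_presence[m] for a in annotations] for m in MATRICES}
    return pd.DataFrame(data, index=[a.metabolite_id for a in annotations], dtype=bool)


# ---------------------------------------------------------------------------
# pipeline front end
# ---------------------------------------------------------------------------

class MetaboliteAnnotator:
    """End-to-end annotation pipeline for one parent compound.

    Configured with the parent's neutral formula, a reaction library, the
    composition filter (which carries the MS1 ppm tolerance), intensity
    thresholds, the DPI/NLF libraries and the isomer RT tolerance.
    ``annotate`` runs intensity filtering, candidate enumeration, MS1
    matching, MS2 confirmation and isomer consolidation, returning an
    :class:`AnnotationResult`.
    """

    def __init__(
        self,
        parent: str | ElementalFormula,
        reactions: Optional[Sequence[Reaction]] = None,
        max_steps: int = 4,
        comp_filter: Optional[CompositionFilter] = None,
        thresholds: Optional[IntensityThresholds] = None,
        dpi_library: Optional[Sequence[DiagnosticIon]] = None,
        nl_library: Optional[Sequence[NeutralLoss]] = None,
        rt_tol: float = 0.2,
        ms2_precursor_tol_ppm: float = 20.0,
        ms2_fragment_tol_da: float = 0.01,
    ):
        self.parent = parse_formula(parent) if isinstance(parent, str) else parent
        self.reactions = list(reactions) if reactions is not None else load_reaction_library()
        self.max_steps = max_steps
        self.comp_filter = comp_filter or default_composition_filter()
        self.thresholds = thresholds or IntensityThresholds()
        self.dpi_library = list(dpi_library) if dpi_library is not None else load_dpi_library()
        self.nl_library = list(nl_library) if nl_library is not None else load_neutral_loss_library()
        self.rt_tol = rt_tol
        self.ms2_precursor_tol_ppm = ms2_precursor_tol_ppm
        self.ms2_fragment_tol_da = ms2_fragment_tol_da
        self._candidates: Optional[List[CandidateMetabolite]] = None

    def candidates(self) -> List[CandidateMetabolite]:
        """Enumerated candidate metabolites (cached)."""
        if self._candidates is None:
            self._candidates = enumerate_candidates(
                self.parent,
                self.reactions,
                max_steps=self.max_steps,
                comp_filter=self.comp_filter,
                adducts=("[M-H]-", "[M+H]+"),
            )
        return self._candidates

    def annotate(
        self,
        peaks: Sequence[Peak],
        spectra: Sequence[MS2Spectrum] = (),
        consolidate_by: str = "rt",
    ) -> "AnnotationResult":
        """Run the pipeline. ``consolidate_by`` is "rt" (cluster same-formula
        observations by retention time) or "feature_id" (group by carried
        feature labels, e.g. from a PRM inclusion list or a synthetic run)."""
        if consolidate_by not in ("rt", "feature_id"):
            raise ValueError("consolidate_by must be 'rt' or 'feature_id'")
        kept = filter_by_intensity(peaks, self.thresholds)
        matches = match_ms1(
            self.candidates(), kept, max_ppm=self.comp_filter.max_ppm,
        )
        evidences = []
        for match in matches:
            dpi_hits: List = []
            nl_hits: List = []
            for spectrum in associate_spectra(
                match.peak, spectra,
                precursor_tol_ppm=self.ms2_precursor_tol_ppm, rt_tol=self.rt_tol,
            ):
                dpi_hits.extend(match_dpis(spectrum, self.dpi_library))
                nl_hits.extend(
                    detect_neutral_losses(
                        spectrum, match.peak.mz, self.nl_library,
                        tol_da=self.ms2_fragment_tol_da,
                    )
                )
            evidences.append(
                MatchEvidence(match=match, dpi_hits=tuple(dpi_hits), nl_hits=tuple(nl_hits))
            )

        parent_evs = [e for e in evidences if e.match.candidate.n_steps == 0]
        metab_evs = [e for e in evidences if e.match.candidate.n_steps > 0]
        records = consolidate_isomers(
            metab_evs, rt_tol=self.rt_tol, use_feature_ids=consolidate_by == "feature_id",
        )
        parent_records = (
            consolidate_isomers(parent_evs, rt_tol=self.rt_tol,
                                use_feature_ids=consolidate_by == "feature_id")
            if parent_evs else []
        )
        matched_peaks = {id(e.match.peak) for e in evidences}
        unmatched = [p for p in kept if id(p) not in matched_peaks]
        return AnnotationResult(
            annotations=records,
            parent_annotations=parent_records,
            unmatched_peaks=unmatched,
            annotator=self,
        )


@dataclass
class AnnotationResult:
    """Pipeline output: metabolite records, parent records, leftovers."""

    annotations: List[AnnotatedMetabolite]
    parent_annotations: List[AnnotatedMetabolite]
    unmatched_peaks: List[Peak]
    annotator: MetaboliteAnnotator = field(repr=False, default=None)

    @property
    def presence_matrix(self) -> pd.DataFrame:
        return build_presence_matrix(self.annotations)

    def matrix_counts(self) -> Dict[str, int]:
        """Distinct metabolites per matrix; 'plasma' is the union of the
        three plasma preparations; 'total' counts all records."""
        pm = self.presence_matrix
        counts = {m: int(pm[m].sum()) for m in MATRICES}
        counts["plasma"] = int(pm[list(PLASMA_MATRICES)].any(axis=1).sum()) if len(pm) else 0
        counts["total"] = len(self.annotations)
        return counts

    def to_frame(self) -> pd.DataFrame:
        """One row per metabolite record, in report column order."""
        rows = []
        for a in self.annotations:
            cand = a.candidate
            match = a.representative.match
            ion = cand.formula - parse_formula("H")
            evidence = ";".join(
                sorted({f"DPI:{i.label}" for i, _ in a.dpi_hits}
                       | {f"NL:{l.label}" for l, _, _ in a.nl_hits})
            )
            row = {
                "metabolite_id": a.metabolite_id,
                "rt_min": round(a.rt, 2),
                "ion_formula": ion.hill(),
                "theoretical_mz": round(cand.theoretical_mz["[M-H]-"], 5),
                "experimental_mz": round(match.peak.mz, 5),
                "rdb": cand.rdb_ion,
                "ppm_error": round(match.ppm, 3),
                "reaction_path": cand.path_label,
                "ms2_evidence": evidence,
                "confidence": a.confidence,
            }
            for m in MATRICES:
                row[m] = "+" if a.matrix_presence[m] else "-"
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable run summary."""
        counts = self.matrix_counts()
        lines = [
            f"annotated metabolites: {counts['total']}",
            f"parent records:        {len(self.parent_annotations)}",
            f"unmatched peaks:       {len(self.unmatched_peaks)}",
            "per-matrix counts (plasma = union of PM/PA/PS):",
            f"  plasma {counts['plasma']}  urine {counts['U']}  feces {counts['F']}"
            f"  liver {counts['L']}  liver microsome {counts['LM']}",
            "confidence tiers: "
            + "  ".join(
                f"{tier}={sum(1 for a in self.annotations if a.confidence == tier)}"
                for tier in "ABC"
            ),
        ]
        return "\n".join(lines)
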