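"""Annotation of observed spectra against enumerated candidates.

A spectrum matches a candidate when the relative precursor mass error is
within the configured ppm tolerance. Samples are one-precursor-per-culture:
when a spectrum carries a fed-precursor label and the candidate derives from
a precursor, the two must agree, which disambiguates isobaric candidates
across samples. Within a sample, isobaric co-candidates are always reported
together, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .assembly import AssembledProduct
from .chemcore import PrecursorAmine
from .fragmenter import fragment_coverage, predict_fragments

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "MatchResult",
    "IncorporationReport",
    "match_spectra",
    "summarize_incorporation",
]

#: Default precursor-match tolerance; the worst calc/obs gap in the reference
#: data (~4.6 ppm) sits comfortably inside it.
DEFAULT_TOL_PPM = 10.0

#: Candidates within this absolute mass gap (Da) are treated as isobars.
_ISOBAR_EPS = 1e-6


@dataclass
class Spectrum:
    """One observed precursor m/z with its fragment peak list.

    ``fed_precursor`` is the registry reference number of the precursor fed
    to the culture the spectrum came from (None when unknown/withheld).
    Fragment peaks above precursor + 1.0 are physically unassignable to the
    precursor and are moved to ``unassignable`` with a warning.
    """

    sample: str
    precursor_mz: float
    fragments: list[float] = field(default_factory=list)
    intensities: Optional[list[float]] = None
    fed_precursor: Optional[int] = None
    unassignable: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        ceiling = self.precursor_mz + 1.0
        bad = [mz for mz in self.fragments if mz >= ceiling]
        if bad:
            logger.warning(
                "spectrum %s: %d fragment peak(s) above precursor m/z reported as"
                " unassignable: %s",
                self.sample,
                len(bad),
                bad,
            )
            self.fragments = [mz for mz in self.fragments if mz < ceiling]
            self.unassignable = list(self.unassignable) + bad
        if self.fed_precursor is None and self.sample.isdigit():
            self.fed_precursor = int(self.sample)


@dataclass(frozen=True)
class MatchResult:
    """One annotated precursor match."""

    sample: str
    observed_mz: float
    candidate_id: str
    calc_mz: float
    ppm_error: float
    co_candidates: tuple[str, ...] = ()
    fragment_coverage: Optional[float] = None


@dataclass
class IncorporationReport:
    """Per-precursor partial/full incorporation flags with supporting matches."""

    partial: dict[int, str]
    full: dict[int, str]
    supporting: dict[int, list[MatchResult]]


def match_spectra(
    spectra: Sequence[Spectrum],
    candidates: Sequence[AssembledProduct],
    tol_ppm: float = DEFAULT_TOL_PPM,
    respect_labels: bool = True,
    with_fragments: bool = False,
) -> list[MatchResult]:
    """Annotate each spectrum with every candidate within tolerance.

    One :class:`MatchResult` is emitted per (spectrum, matching candidate);
    isobaric co-candidates (identical calculated mass to 1e-6 Da) are listed
    on each result. Results are sorted by sample label, then |ppm error|,
    then candidate id.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if not spectra:
        return []
    if not candidates:
        raise ValueError("candidate list must be non-empty")

    predicted_cache: dict[str, list] = {}
    results: list[MatchResult] = []
    for spectrum in spectra:
        hits: list[tuple[AssembledProduct, float]] = []
        for candidate in candidates:
            if (
                respect_labels
                and spectrum.fed_precursor is not None
                and candidate.precursor_id is not None
                and candidate.precursor_id != spectrum.fed_precursor
            ):
                continue
            calc = candidate.mz
            ppm = (spectrum.precursor_mz - calc) / calc * 1e6
            if abs(ppm) <= tol_ppm:
                hits.append((candidate, ppm))
        for candidate, ppm in hits:
            co = tuple(
                sorted(
                    other.id
                    for other, _ in hits
                    if other.id != candidate.id
                    and abs(other.mz - candidate.mz) <= _ISOBAR_EPS
                )
            )
            coverage = None
            if with_fragments and spectrum.fragments:
                if candidate.id not in predicted_cache:
                    predicted_cache[candidate.id] = predict_fragments(candidate)
                coverage, _ = fragment_coverage(
                    predicted_cache[candidate.id], spectrum.fragments, tol_ppm
                )
            results.append(
                MatchResult(
                    sample=spectrum.sample,
                    observed_mz=spectrum.precursor_mz,
                    candidate_id=candidate.id,
                    calc_mz=candidate.mz,
                    ppm_error=ppm,
                    co_candidates=co,
                    fragment_coverage=coverage,
                )
            )
    results.sort(key=lambda r: (r.sample, abs(r.ppm_error), r.candidate_id))
    return results


def summarize_incorporation(
    results: Iterable[MatchResult],
    registry: Sequence[PrecursorAmine],
    candidates: Sequence[AssembledProduct] = (),
    min_fragment_coverage: Optional[float] = None,
) -> IncorporationReport:
    """Reduce match results to per-precursor partial/full flags.

    ``partial`` is "yes" when any intermediate of the precursor matched;
    ``full`` when any capped analog did; "nd" otherwise. When
    ``min_fragment_coverage`` is set, matches whose coverage is known and
    below the threshold are ignored.
    """
    kind_by_id = {c.id: c for c in candidates}
    partial = {p.ref_no: "nd" for p in registry}
    full = {p.ref_no: "nd" for p in registry}
    supporting: dict[int, list[MatchResult]] = {p.ref_no: [] for p in registry}
    for result in results:
        candidate = kind_by_id.get(result.candidate_id)
        if candidate is None or candidate.precursor_id is None:
            continue
        if (
            min_fragment_coverage is not None
            and result.fragment_coverage is not None
            and result.fragment_coverage < min_fragment_coverage
        ):
            continue
        ref = candidate.precursor_id
        if ref not in partial:
            continue
        if candidate.kind == "intermediate":
            partial[ref] = "yes"
        elif candidate.kind == "analog":
            full[ref] = "yes"
        supporting[ref].append(result)
    return IncorporationReport(partial=partial, full=full, supporting=supporting)
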