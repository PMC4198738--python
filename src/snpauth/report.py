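"""Aggregate per-sample authentication evidence into one verdict.

The decision cascade distinguishes the possible reasons a sample fails
authentication: an identity-level match to the wrong strain is a
misidentification; a secondary background with positionally clustered
discordance is a mixed (introgressed) background; a significant BAF
deviation is contamination; chromosome-level copy-number change is
aneuploidy. A sample can carry several problems at once — the first
triggered stage gives the primary verdict and the rest are appended as
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cna import CnaCall
from .matching import MatchResult, SecondaryMatch

VERDICTS = (
    "authenticated",
    "misidentified",
    "mixed_background",
    "contaminated",
    "aneuploid",
    "unresolved",
)


@dataclass
class AuthenticationReport:
    sample_id: str
    reported_strain: str | None
    match: MatchResult
    verdict: str
    contamination_fraction: float | None = None
    contamination_significant: bool = False
    cna_calls: list[CnaCall] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    notes: str = ""


def _strain_matches(best_strain: str | None, reported: str | None) -> bool:
    if best_strain is None or reported is None:
        return False
    return best_strain == reported


def compile_report(
    match: MatchResult,
    reported_strain: str | None,
    best_match_strain: str | None,
    secondary: SecondaryMatch | None = None,
    contamination: tuple[float, bool] | None = None,
    cna_calls: list[CnaCall] | None = None,
) -> AuthenticationReport:
    """Run the decision cascade over the per-module results."""
    cna_calls = cna_calls or []
    aneuploid_chroms = [
        c.chromosome for c in cna_calls if c.classification != "normal"
    ]
    flags: list[str] = []
    notes: list[str] = []

    contaminated = contamination is not None and contamination[1]
    if match.verdict == "identity":
        if _strain_matches(best_match_strain, reported_strain):
            verdict = "authenticated"
        else:
            verdict = "misidentified"
            notes.append(
                f"identity match to {match.best_reference_id!r} "
                f"({best_match_strain!r}), reported {reported_strain!r}"
            )
    elif secondary is not None and secondary.interpretation == "introgression":
        verdict = "mixed_background"
        notes.append(
            f"secondary background {secondary.reference_id!r} "
            f"(score {secondary.score_on_discordant:.2f}, clustered discordance)"
        )
    elif contaminated:
        verdict = "contaminated"
    elif aneuploid_chroms:
        verdict = "aneuploid"
    else:
        verdict = "unresolved"

    if contaminated and verdict != "contaminated":
        flags.append("contaminated")
    if aneuploid_chroms and verdict != "aneuploid":
        flags.append("aneuploid")
    if secondary is not None and secondary.interpretation == "contamination_suspect":
        flags.append("secondary_background_unclustered")
    if aneuploid_chroms:
        notes.append("copy-number change on chromosome(s) " + ", ".join(aneuploid_chroms))

    return AuthenticationReport(
        sample_id=match.query_sample_id,
        reported_strain=reported_strain,
        match=match,
        verdict=verdict,
        contamination_fraction=None if contamination is None else contamination[0],
        contamination_significant=contaminated,
        cna_calls=cna_calls,
        flags=flags,
        notes="; ".join(notes),
    )
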