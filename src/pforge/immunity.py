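"""Integration-dependent immunity: repressor-form reconstruction.

In integration-dependent immunity systems the phage attachment site attP
lies inside the immunity repressor gene near its 3' end.  The virion
(excised, circular) genome therefore encodes a repressor with extra
C-terminal residues carrying an ssrA-like degradation tag; integration
truncates the gene at attR, removing the tag and stabilizing the
prophage-encoded repressor.  This module reconstructs both forms from a
lysogen sequence and scans C-termini for a configurable ssrA-like motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ._seq import STOP_CODONS, check_dna, translate
from .attsite import ExcisionResult, excise
from .errors import ConfigError, InputError

#: Ala-Ala terminus preceded by a small/nonpolar residue, within the
#: C-terminal window.  The canonical tag (...YALAA) matches.  Fully
#: user-overridable; the exact tag residues differ between systems.
DEFAULT_SSRA_PATTERN = r"[AGCSTVLIMP]AA$"


@dataclass(frozen=True)
class RepressorForms:
    """Prophage- vs virion-encoded repressor proteins.

    ``extension`` holds the C-terminal residues unique to the virion form
    (empty when the locus has no integration-dependent architecture).
    """

    prophage_protein: str
    virion_protein: str
    extension: str
    integration_dependent: bool
    tag_hit: tuple[str, int] | None = None  # (matched text, offset in protein)


def reconstruct_repressor_forms(
    lysogen: str,
    attL_interval: tuple[int, int],
    attR_interval: tuple[int, int],
    crossover: tuple[int, ...],
    repressor_start: int,
    tag_pattern: str | None = DEFAULT_SSRA_PATTERN,
) -> RepressorForms:
    """Reconstruct the repressor protein in its integrated and excised frames.

    ``repressor_start`` is the 1-based position of the repressor start codon
    on the lysogen forward strand; the gene must lie inside the prophage
    (between attL end and attR), reading toward attR.  The prophage form is
    translated in the integrated frame; the virion form is translated in
    the excised circular frame produced by :func:`pforge.attsite.excise`,
    where the gene reads through attP.  ``extension`` is the virion-only
    suffix after the shared prefix; the architecture is called
    integration-dependent when the virion open reading frame crosses the
    attP junction (extension necessarily non-empty).
    """
    lysogen = check_dna(lysogen, name="lysogen")
    exc: ExcisionResult = excise(lysogen, attL_interval, attR_interval, crossover)

    l2 = attL_interval[1]
    r1 = attR_interval[0]
    if not (l2 < repressor_start < r1):
        raise InputError(
            "repressor start must lie inside the prophage interior "
            f"(attL end {l2} < start < attR start {r1})"
        )
    if lysogen[repressor_start - 1 : repressor_start + 2] != "ATG":
        raise InputError("no ATG at the given repressor start")

    prophage_protein = translate(lysogen[repressor_start - 1 :])

    # map the start into the excised circle: interior begins after attP
    offset_in_interior = repressor_start - 1 - l2
    start_in_virion = len(exc.attP) + offset_in_interior
    circle = exc.virion
    doubled = circle[start_in_virion:] + circle  # read across the junction
    virion_protein = translate(doubled)

    # does the virion ORF read through the attP junction?
    junction = len(circle) - start_in_virion  # bases until circle origin
    orf_nt = 3 * (len(virion_protein) + 1)  # incl. stop
    integration_dependent = orf_nt > junction

    common = 0
    while (
        common < min(len(prophage_protein), len(virion_protein))
        and prophage_protein[common] == virion_protein[common]
    ):
        common += 1
    extension = virion_protein[common:]

    tag = scan_ssra_tag(virion_protein, pattern=tag_pattern) if virion_protein else None
    return RepressorForms(
        prophage_protein=prophage_protein,
        virion_protein=virion_protein,
        extension=extension,
        integration_dependent=integration_dependent,
        tag_hit=tag,
    )


def scan_ssra_tag(
    protein: str,
    pattern: str | None = DEFAULT_SSRA_PATTERN,
    window: int = 15,
) -> tuple[str, int] | None:
    """Match an ssrA-like degradation motif in the C-terminal window.

    Returns ``(matched_text, offset_in_protein)`` or ``None``.  An empty or
    ``None`` pattern disables the scan.
    """
    if not protein:
        raise InputError("protein is empty")
    if not pattern:
        return None
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ConfigError(f"malformed ssrA pattern {pattern!r}: {exc}") from exc
    tail_start = max(0, len(protein) - window)
    m = rx.search(protein[tail_start:])
    if m is None:
        return None
    return m.group(0), tail_start + m.start()
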