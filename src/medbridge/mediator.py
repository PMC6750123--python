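"""Knowledge-based registration workflows: direct, single- and multi-mediator.

Instead of registering a subject straight to the template, the subject is
registered to each member of a library of intermediate images (mediators)
whose transforms into template space are already known and quality-verified.
The mediator most similar to the registered subject is selected — by SSD
after histogram matching, by mutual information, or by an oracle Dice when
ground-truth masks exist — and the subject reaches template space through
the composition

    T_subject->mediator->template = T_subject->mediator o T_mediator->template

which, in the pull-back convention used throughout, is a single matrix
product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .registration import (
    RegistrationConfig,
    register_affine,
    resample,
    resample_mask_nn,
)
from .similarity import dice, histogram_match, mutual_information, ssd
from .volumes_io import AffineTransform, BinaryMask, MediatorLibrary, Volume

__all__ = [
    "CandidateRecord",
    "SelectionResult",
    "CRITERIA",
    "DIRECT_ID",
    "compose",
    "register_direct",
    "evaluate_candidates",
    "select_from",
    "run_multi_mediator",
    "apply_to_template",
]

CRITERIA = ("ssd", "mi", "oracle_dice")
DIRECT_ID = "__direct__"


@dataclass
class CandidateRecord:
    """One mediator's scores and composed subject->template transform."""

    mediator_id: str
    subject_to_mediator: AffineTransform
    composed: AffineTransform
    ssd: Optional[float] = None
    mi: Optional[float] = None
    dice_oracle: Optional[float] = None


@dataclass
class SelectionResult:
    """Per-mediator candidate records and the criterion-optimal choice."""

    candidates: list[CandidateRecord] = field(default_factory=list)
    criterion: str = "ssd"
    chosen_id: str = ""
    chosen_transform: Optional[AffineTransform] = None

    def record(self, mediator_id: str) -> CandidateRecord:
        for c in self.candidates:
            if c.mediator_id == mediator_id:
                return c
        raise KeyError(mediator_id)


def compose(t_ab: AffineTransform, t_bc: AffineTransform) -> AffineTransform:
    """Compose pull-backs a->b and b->c into a->c.

    For a world point p in space c the result applies ``t_bc`` first, then
    ``t_ab``; the matrix is the plain product ``t_ab.matrix @ t_bc.matrix``.
    Space labels must chain.
    """
    if t_ab.to_space != t_bc.from_space:
        raise ValueError(
            f"space labels do not chain: {t_ab.from_space}->{t_ab.to_space} "
            f"with {t_bc.from_space}->{t_bc.to_space}"
        )
    return AffineTransform(t_ab.matrix @ t_bc.matrix, t_ab.from_space, t_bc.to_space)


def register_direct(
    subject: Volume,
    library: MediatorLibrary,
    cfg: RegistrationConfig | None = None,
    subject_label: str = "subject",
) -> CandidateRecord:
    """Pairwise direct registration of the subject to the library template."""
    result = register_affine(subject, library.template, cfg)
    t = result.transform.relabel(subject_label, library.space_label)
    return CandidateRecord(mediator_id=DIRECT_ID, subject_to_mediator=t, composed=t)


def evaluate_candidates(
    subject: Volume,
    library: MediatorLibrary,
    criteria: Iterable[str] = ("ssd",),
    cfg: RegistrationConfig | None = None,
    subject_mask: Optional[BinaryMask] = None,
    subject_label: str = "subject",
    match_levels: int = 256,
    mi_bins: int = 64,
) -> list[CandidateRecord]:
    """Register the subject to every mediator once, scoring all ``criteria``.

    SSD and MI are computed on the mediator's grid with the subject
    resampled onto it (scores follow registration between the subject and
    mediator images); SSD sees the mediator histogram-matched to the
    resampled subject, MI sees the raw intensities.  ``oracle_dice``
    carries the subject mask into template space through each composed
    transform and scores it against the template mask.  One record per
    library entry, in library order.
    """
    if len(library) == 0:
        raise ValueError("empty mediator library")
    criteria = tuple(criteria)
    for c in criteria:
        if c not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}, got {c!r}")
    if "oracle_dice" in criteria and subject_mask is None:
        raise ValueError("oracle_dice requires the subject brain mask")

    records: list[CandidateRecord] = []
    for entry in library.entries:
        reg = register_affine(subject, entry.volume, cfg)
        t_s2m = reg.transform.relabel(subject_label, entry.to_template.from_space)
        composed = compose(t_s2m, entry.to_template)
        rec = CandidateRecord(
            mediator_id=entry.id, subject_to_mediator=t_s2m, composed=composed
        )
        if "ssd" in criteria or "mi" in criteria:
            subj_on_med = resample(subject, entry.volume, t_s2m)
            if "ssd" in criteria:
                matched = histogram_match(entry.volume, subj_on_med, match_levels)
                rec.ssd = ssd(matched, subj_on_med)
            if "mi" in criteria:
                rec.mi = mutual_information(entry.volume, subj_on_med, mi_bins)
        if "oracle_dice" in criteria:
            moved = resample_mask_nn(subject_mask, library.template_mask, composed)
            rec.dice_oracle = dice(moved, library.template_mask)
        records.append(rec)
    return records


def select_from(candidates: list[CandidateRecord], criterion: str) -> SelectionResult:
    """Pick the criterion optimum (min SSD; max MI or oracle Dice).

    Ties break toward the first candidate in library order (argmin/argmax
    return the first extremum).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    attr = {"ssd": "ssd", "mi": "mi", "oracle_dice": "dice_oracle"}[criterion]
    scores = [getattr(c, attr) for c in candidates]
    if any(s is None for s in scores):
        raise ValueError(f"candidates lack {criterion} scores")
    arr = np.asarray(scores, dtype=float)
    best = int(np.argmin(arr)) if criterion == "ssd" else int(np.argmax(arr))
    chosen = candidates[best]
    return SelectionResult(
        candidates=candidates,
        criterion=criterion,
        chosen_id=chosen.mediator_id,
        chosen_transform=chosen.composed,
    )


def run_multi_mediator(
    subject: Volume,
    library: MediatorLibrary,
    criterion: str = "ssd",
    cfg: RegistrationConfig | None = None,
    subject_mask: Optional[BinaryMask] = None,
    subject_label: str = "subject",
    match_levels: int = 256,
    mi_bins: int = 64,
) -> SelectionResult:
    """Register the subject to every mediator and select the criterion optimum.

    ``criterion`` is ``"ssd"`` (smallest SSD between each histogram-matched
    mediator and the subject resampled onto it), ``"mi"`` (largest mutual
    information), or ``"oracle_dice"`` (largest Dice of the subject mask
    carried to template space against the template mask — the 'true best'
    upper bound, requiring ``subject_mask``).  Ties break toward the first
    entry in library order.  Deterministic given the configuration.
    """
    records = evaluate_candidates(
        subject, library, (criterion,), cfg, subject_mask, subject_label,
        match_levels, mi_bins,
    )
    return select_from(records, criterion)


def apply_to_template(
    subject_or_mask: Volume | BinaryMask,
    composed: AffineTransform,
    library: MediatorLibrary,
    interpolation: str = "auto",
) -> Volume | BinaryMask:
    """Resample an image or mask into the template grid via a composed transform.

    Masks travel with nearest-neighbour interpolation (values stay {0,1});
    images with trilinear.  ``interpolation`` may force ``"nearest"`` or
    ``"trilinear"``; ``"auto"`` picks by input type.
    """
    is_mask = isinstance(subject_or_mask, BinaryMask)
    if interpolation == "auto":
        interpolation = "nearest" if is_mask else "trilinear"
    if interpolation == "nearest" and is_mask:
        return resample_mask_nn(subject_or_mask, library.template, composed)
    vol = subject_or_mask.as_volume() if is_mask else subject_or_mask
    order = 0 if interpolation == "nearest" else 1
    return resample(vol, library.template, composed, order=order)
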