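"""Cohort-level record container shared by the alignment, stats and synthetic modules."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class CohortRecord:
    """One individual's demographics, grades, alignment and motion outcomes.

    All clinical fields are optional so the same container serves both the
    fully populated in-study tables and the stubs emitted by the synthetic
    cohort generator (which only knows ``id``, ``label`` and ``seed``).

    Attributes
    ----------
    id : str
        Individual identifier (e.g. "1".."10", "E1".."E3", or synthetic ids).
    sex : str, optional
        "M" or "F".
    age : float, optional
        Years.
    ndi_points : float, optional
        Neck Disability Index, raw points (inclusion requires <= 4).
    ndi_pct : float, optional
        NDI expressed as a percentage of the maximum score.
    ks : dict, optional
        Kellgren score per segment label, ordinal 0-4 (4 excludes).
    sa : dict, optional
        Sagittal alignment (Cobb angle, degrees; lordosis positive) keyed by
        "C2-C7" or a segment label.
    srom : dict, optional
        ``{timepoint: {segment: degrees}}`` segmental range of motion.
    trom : dict, optional
        ``{timepoint: degrees}`` total C4-C7 range of motion.
    sequence : dict, optional
        ``{timepoint: '+'|'-'}`` presence of the normal extension sequence.
    label : str, optional
        Synthetic motion label ("young_consistent" | "elderly_inconsistent" |
        "custom").
    seed : int, optional
        Seed used to generate the synthetic recording, if any.
    """

    id: str
    sex: str | None = None
    age: float | None = None
    ndi_points: float | None = None
    ndi_pct: float | None = None
    ks: dict[str, int] | None = None
    sa: dict[str, float] | None = None
    srom: dict[str, dict[str, float]] = field(default_factory=dict)
    trom: dict[str, float] = field(default_factory=dict)
    sequence: dict[str, str] = field(default_factory=dict)
    label: str | None = None
    seed: int | None = None
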