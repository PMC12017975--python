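"""Study-level containers: observer groups and per-case delineation sets."""

from __future__ import annotations

from dataclasses import dataclass, field

from .consensus import ObserverSet

__all__ = ["GROUP_RAD", "GROUP_GTV_MINUS", "GROUP_GTV_PLUS", "GROUPS", "CaseStudy"]

GROUP_RAD = "RAD"
GROUP_GTV_MINUS = "GTV-"
GROUP_GTV_PLUS = "GTV+"
GROUPS = (GROUP_RAD, GROUP_GTV_MINUS, GROUP_GTV_PLUS)


@dataclass
class CaseStudy:
    """One case: its id, subtype tags, and per-group observer delineations.

    ``groups`` maps a group label (``RAD``, ``GTV-``, ``GTV+``) to the
    :class:`~contour_iov.consensus.ObserverSet` holding that group's returned
    contours for this case. ``subtypes`` carries recurrence-type tags
    (e.g. ``lateral``, ``fibrotic``); a case may carry several.
    ``metadata`` records generation parameters for synthetic cases.
    """

    case_id: str
    groups: dict[str, ObserverSet]
    subtypes: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError(f"case {self.case_id!r} has no observer groups")
        for label, obs in self.groups.items():
            if len(obs) < 1:
                raise ValueError(f"group {label!r} of case {self.case_id!r} is empty")
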