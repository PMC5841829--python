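"""The cell agent: position, velocity history, phenotype, custom state."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from multicell.phenotype import Phenotype


@dataclass
class AttachmentLink:
    """Symmetric elastic attachment to a partner cell with spring
    coefficient ``k`` (1/min): each partner gains velocity
    ``k (x_partner - x_self)``."""

    partner: "Cell"
    k: float


class Cell:
    """One agent.

    Velocities are computed by the mechanics phase against a frozen
    position snapshot; ``previous_velocity`` supports the second-order
    Adams-Bashforth position update.  ``custom`` holds model-specific
    scalars (oncoprotein expression, drug damage, cargo receptor, ...).
    """

    __slots__ = (
        "id", "type_name", "position", "velocity", "previous_velocity",
        "phenotype", "custom", "attachments",
        "flagged_for_division", "flagged_for_removal",
        "update_phenotype", "custom_cell_rule",
    )

    def __init__(self, cell_id: int, phenotype: Phenotype, position,
                 type_name: str = "default"):
        self.id = cell_id
        self.type_name = type_name
        self.position = np.asarray(position, dtype=float).copy()
        self.velocity = np.zeros(3)
        self.previous_velocity: Optional[np.ndarray] = None
        self.phenotype = phenotype
        self.custom: dict = {}
        self.attachments: list[AttachmentLink] = []
        self.flagged_for_division = False
        self.flagged_for_removal = False
        #: hook(cell, field, dt) run each cell step before cycle/death
        self.update_phenotype: Optional[Callable] = None
        #: hook(cell, simulator) run each mechanics step (may add velocity)
        self.custom_cell_rule: Optional[Callable] = None

    # --------------------------------------------------- secretion protocol

    @property
    def volume(self) -> float:
        return self.phenotype.volume.V

    @property
    def radius(self) -> float:
        return self.phenotype.volume.radius

    @property
    def secretion_rates(self) -> np.ndarray:
        return self.phenotype.secretion.secretion

    @property
    def uptake_rates(self) -> np.ndarray:
        return self.phenotype.secretion.uptake

    @property
    def saturation_densities(self) -> np.ndarray:
        return self.phenotype.secretion.saturation

    @property
    def is_dead(self) -> bool:
        death = self.phenotype.death
        return death is not None and death.dead

    # ------------------------------------------------------------- linkage

    def attach_to(self, other: "Cell", k: float) -> None:
        """Create a symmetric elastic link (no-op if already linked)."""
        if any(l.partner is other for l in self.attachments):
            return
        self.attachments.append(AttachmentLink(other, k))
        other.attachments.append(AttachmentLink(self, k))

    def detach_from(self, other: "Cell") -> None:
        self.attachments = [l for l in self.attachments if l.partner is not other]
        other.attachments = [l for l in other.attachments if l.partner is not self]

    def detach_all(self) -> None:
        for link in list(self.attachments):
            self.detach_from(link.partner)

    def __repr__(self) -> str:  # pragma: no cover
        x, y, z = self.position
        return (f"Cell(id={self.id}, type={self.type_name!r}, "
                f"pos=({x:.1f}, {y:.1f}, {z:.1f}), V={self.volume:.0f})")
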