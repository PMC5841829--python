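"""Showcase simulations: hanging-drop spheroid, ductal carcinoma in situ,
biorobots, anti-cancer biorobots, tumor heterogeneity, tumor-immune.

Each showcase is a builder returning a ready-to-run
:class:`~multicell.simulator.Simulator` at desk scale (hundreds to a
few thousand cells); the published systems are orders of magnitude
larger, so these are scaled surrogates that preserve the rules and the
qualitative emergent behaviors.
"""

from multicell.samples.spheroid import build_spheroid
from multicell.samples.dcis import build_dcis
from multicell.samples.biorobots import build_biorobots
from multicell.samples.anticancer import build_anticancer_biorobots
from multicell.samples.heterogeneity import build_heterogeneity
from multicell.samples.immune import build_tumor_immune

REGISTRY = {
    "spheroid": build_spheroid,
    "dcis": build_dcis,
    "biorobots": build_biorobots,
    "anticancer_biorobots": build_anticancer_biorobots,
    "heterogeneity": build_heterogeneity,
    "tumor_immune": build_tumor_immune,
}


def build(name: str, seed: int | None = None, **overrides):
    """Build a showcase simulator by name."""
    from multicell.errors import ConfigurationError

    try:
        builder = REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown sample model {name!r}; available: {sorted(REGISTRY)}") from None
    return builder(seed=seed, **overrides)

__all__ = ["REGISTRY", "build", "build_spheroid", "build_dcis",
           "build_biorobots", "build_anticancer_biorobots",
           "build_heterogeneity", "build_tumor_immune"]
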