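"""National-registry attack-treatment tallies and derived proportions.

The study cohort is drawn from a national primary-immunodeficiency registry;
the registry records, for each documented swelling attack, whether it was
treated and with which on-demand therapy.  The bundled constant holds the
published tally for the Czech registry, March 2012 - October 2021 (6,945
attacks in 166 patients); :func:`treatment_percentages` derives the headline
proportions from any such tally.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TreatmentTally:
    """Counts of recorded attacks by on-demand treatment modality."""

    total_attacks: int
    treated: int
    icatibant: int
    rh_c1inh: int      # recombinant human C1 inhibitor
    pnf_c1inh: int     # plasma-derived, pasteurized/nanofiltered C1 inhibitor
    nf_c1inh: int      # plasma-derived, nanofiltered C1 inhibitor
    attenuated_androgens: int
    tranexamic_acid: int
    fresh_frozen_plasma: int

    def __post_init__(self) -> None:
        if self.treated > self.total_attacks:
            raise ValueError("treated attacks cannot exceed total attacks")
        if any(v < 0 for v in self.__dict__.values()):
            raise ValueError("counts must be non-negative")


CZECH_REGISTRY_2012_2021 = TreatmentTally(
    total_attacks=6945,
    treated=5691,
    icatibant=3562,
    rh_c1inh=847,
    pnf_c1inh=1002,
    nf_c1inh=83,
    attenuated_androgens=134,
    tranexamic_acid=88,
    fresh_frozen_plasma=10,
)


def treatment_percentages(tally: TreatmentTally, ndigits: int = 1) -> dict[str, float]:
    """Percentage of attacks treated, and of treated attacks per modality.

    The treated fraction is taken over all recorded attacks; each modality's
    share is taken over treated attacks, matching how registries report
    on-demand therapy uptake.  Percentages are rounded to ``ndigits``.
    """
    if tally.total_attacks == 0:
        raise ValueError("empty tally")
    out = {"treated_pct": 100.0 * tally.treated / tally.total_attacks}
    for name in (
        "icatibant",
        "rh_c1inh",
        "pnf_c1inh",
        "nf_c1inh",
        "attenuated_androgens",
        "tranexamic_acid",
        "fresh_frozen_plasma",
    ):
        out[f"{name}_pct"] = 100.0 * getattr(tally, name) / tally.treated
    return {k: round(v, ndigits) for k, v in out.items()}
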