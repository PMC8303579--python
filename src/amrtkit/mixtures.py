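"""Non-isobaric mixture design for retention-time assignment.

Standards are pooled into mixtures for the RT-assignment injections; two
compounds whose precursor m/z values fall within ``delta`` of each other in
either polarity cannot share a mixture, or the DDA isolation window could
co-select them.  Conflicts on the m/z line form a unit-interval graph, which
is perfect: first-fit assignment over compounds sorted by m/z uses exactly as
many mixtures as the largest isobaric clique, the provable minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import pandas as pd

from .library_model import Compound, default_precursor_mz, POSITIVE, NEGATIVE

__all__ = [
    "MixturePlan",
    "species_mz_table",
    "partition_non_isobaric",
    "verify_partition",
]

SpeciesMZ = Mapping[str, Mapping[str, float]]


@dataclass
class MixturePlan:
    """Disjoint mixtures (lists of compound ids) with the separation used."""

    mixtures: list[list[str]]
    delta: float

    @property
    def n_mixtures(self) -> int:
        return len(self.mixtures)

    def mixture_of(self, compound_id: str) -> int:
        for i, mix in enumerate(self.mixtures):
            if compound_id in mix:
                return i
        raise KeyError(compound_id)

    def to_frame(self, species_mz: SpeciesMZ) -> pd.DataFrame:
        rows = []
        for i, mix in enumerate(self.mixtures, start=1):
            for cid in mix:
                row = {"mixture": i, "compound_id": cid}
                row.update({f"mz_{pol}": mz for pol, mz in species_mz[cid].items()})
                rows.append(row)
        return pd.DataFrame(rows)


def species_mz_table(
    compounds: Sequence[Compound],
    polarities: Sequence[str] = (POSITIVE, NEGATIVE),
) -> dict[str, dict[str, float]]:
    """Default precursor m/z per compound and polarity."""
    return {
        c.id: {pol: default_precursor_mz(c.neutral_mass, pol) for pol in polarities}
        for c in compounds
    }


def _conflict(a: Mapping[str, float], b: Mapping[str, float], delta: float) -> bool:
    # a pair conflicting in EITHER polarity conflicts: the mixture is injected
    # once and acquired in both modes
    return any(
        abs(a[pol] - b[pol]) < delta for pol in a.keys() & b.keys()
    )


def partition_non_isobaric(species_mz: SpeciesMZ, delta: float = 1.5) -> MixturePlan:
    """Partition compounds into the minimum number of non-isobaric mixtures.

    ``species_mz`` maps compound id -> {polarity: precursor m/z}.  Compounds
    are sorted by their smallest species m/z (ties by id) and assigned
    first-fit to the earliest mixture with no conflict; on unit-interval
    conflict graphs this greedy colouring is optimal, so the mixture count
    equals the largest set of pairwise-isobaric compounds.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    order = sorted(species_mz, key=lambda cid: (min(species_mz[cid].values()), cid))
    mixtures: list[list[str]] = []
    for cid in order:
        mzs = species_mz[cid]
        for mix in mixtures:
            if not any(_conflict(mzs, species_mz[other], delta) for other in mix):
                mix.append(cid)
                break
        else:
            mixtures.append([cid])
    return MixturePlan(mixtures=mixtures, delta=delta)


def verify_partition(
    plan: MixturePlan, species_mz: SpeciesMZ, delta: Union[float, None] = None
) -> tuple[bool, list[tuple[int, str, str, str, float]]]:
    """Check a mixture plan against the separation constraint.

    Returns ``(ok, violations)`` where each violation is
    ``(mixture_index, id_a, id_b, polarity, separation)``.  A compound present
    in ``species_mz`` but missing from the plan (or planned twice) is a
    coverage error.
    """
    if delta is None:
        delta = plan.delta
    planned = [cid for mix in plan.mixtures for cid in mix]
    if sorted(planned) != sorted(species_mz):
        missing = set(species_mz) - set(planned)
        extra = set(planned) - set(species_mz)
        dup = {cid for cid in planned if planned.count(cid) > 1}
        raise ValueError(
            f"plan does not cover compounds exactly: missing={sorted(missing)[:5]} "
            f"extra={sorted(extra)[:5]} duplicated={sorted(dup)[:5]}"
        )
    violations = []
    for idx, mix in enumerate(plan.mixtures):
        for i, a in enumerate(mix):
            for b in mix[i + 1:]:
                for pol in species_mz[a].keys() & species_mz[b].keys():
                    sep = abs(species_mz[a][pol] - species_mz[b][pol])
                    if sep < delta:
                        violations.append((idx, a, b, pol, sep))
    return (not violations, violations)
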