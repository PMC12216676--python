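"""Scoring a pipeline run against simulator ground truth.

Used by the bundled benchmarks: maps recovered regions back to the seeded
crystals (by majority of contributing cells), then counts recovered true
pairs, cross-crystal false matches and triangulation errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matching import RunResult
from .simulate import GroundTruth

__all__ = ["RunScore", "score_run"]


@dataclass
class RunScore:
    """Counts and errors from one simulated double-mesh run."""

    n_true_pairs: int
    n_recovered: int
    n_false_matches: int
    n_candidates: int
    # per recovered true pair: max abs coordinate error (mm)
    position_errors: list[float] = field(default_factory=list)


def _region_to_crystal(regions, contributors) -> dict[int, int | None]:
    out: dict[int, int | None] = {}
    for region in regions:
        counts: dict[int, int] = {}
        for cell in region.cells:
            for ci in contributors.get(cell, []):
                counts[ci] = counts.get(ci, 0) + 1
        out[region.label] = max(counts, key=counts.get) if counts else None
    return out


def score_run(result: RunResult, truth: GroundTruth) -> RunScore:
    """Compare matched pairs and positions with the seeded ground truth."""
    m1 = _region_to_crystal(result.regions1, truth.contributors[0])
    m2 = _region_to_crystal(result.regions2, truth.contributors[1])
    recovered: set[int] = set()
    false_matches = 0
    errors: list[float] = []
    for m in result.matches:
        ca = m1[m.pair.region_a.label]
        cb = m2[m.pair.region_b.label]
        if ca is not None and ca == cb:
            if ca in truth.true_pairs and ca not in recovered:
                recovered.add(ca)
                err = np.abs(
                    m.position.as_array() - np.asarray(truth.crystals[ca].position)
                )
                errors.append(float(err.max()))
        else:
            false_matches += 1
    return RunScore(
        n_true_pairs=len(truth.true_pairs),
        n_recovered=len(recovered),
        n_false_matches=false_matches,
        n_candidates=len(result.candidates),
        position_errors=errors,
    )
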