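import numpy as np
import pytest

import leafmorph as lm
from leafmorph.margin_patterning import cp_permitted_mask, find_insertion_sites
from leafmorph.simulator import step

PRESET_NAMES = [
    "simple-cordate",
    "compound-teeth",
    "palmate-lobed",
    "palmate-simple-lobes",
    "pinnate-compound",
]


class PresetRun:
    """Final state of one preset run plus per-step patterning audits."""

    def __init__(self, name):
        self.name = name
        self.params, self.preset = lm.get_preset(name)
        state = lm.make_primordium(self.params, self.preset)
        self.residual_sites = 0  # qualifying intervals left after any step
        self.blocked_cp_states = 0  # CPs carrying a blocking morphogen
        blockers = [
            n for n, r in self.params.morphogens.items() if r.blocks_cp
        ]
        for _ in range(self.params.n_steps):
            state = step(state, self.params)
            self.residual_sites += len(
                find_insertion_sites(state.margin, state.veins, self.params, state.age)
            )
            for i in state.margin.cp_indices():
                if any(state.margin.points[i].has(n) for n in blockers):
                    self.blocked_cp_states += 1
        self.final = state


@pytest.fixture(scope="session")
def preset_runs():
    """All five packaged presets run to completion (with meshes)."""
    return {name: PresetRun(name) for name in PRESET_NAMES}


@pytest.fixture(scope="session")
def simple_final(preset_runs):
    return preset_runs["simple-cordate"].final


@pytest.fixture()
def midvein_state():
    """Minimal leaf: rectangle-ish margin with a single vertical midvein."""
    params = lm.Params(lambda_cp=10.0, delta_seg=0.1, dt=0.1)
    pts = np.array(
        [
            [-0.2, 0.0],
            [-0.25, 1.0],
            [-0.15, 2.0],
            [0.0, 2.4],
            [0.15, 2.0],
            [0.25, 1.0],
            [0.2, 0.0],
        ]
    )
    preset = lm.PrimordiumPreset(points=pts, apex_index=3)
    return lm.make_primordium(params, preset), params
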