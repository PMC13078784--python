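"""Shared configuration for the numbered analysis drivers.

One seed and one condition panel drive every script so their outputs are
mutually consistent; each script re-runs the pipeline stages it needs (the
simulation is seeded, so recomputation is exact) and writes its tables
under results/.
"""

from pathlib import Path

from memfret.pipeline import ConditionConfig, RunConfig

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

#: The anionic-lipid titration panel: POPS content with and without EGF.
CONDITIONS = [
    ConditionConfig("0% POPS -EGF", egf=False),
    ConditionConfig("0% POPS +EGF", egf=True, pair_with="0% POPS -EGF"),
    ConditionConfig("15% POPS -EGF", egf=False),
    ConditionConfig("15% POPS +EGF", egf=True, pair_with="15% POPS -EGF"),
    ConditionConfig("30% POPS -EGF", egf=False),
    ConditionConfig("30% POPS +EGF", egf=True, pair_with="30% POPS -EGF"),
    ConditionConfig("60% POPS -EGF", egf=False),
    ConditionConfig("60% POPS +EGF", egf=True, pair_with="60% POPS -EGF"),
]


def make_config(stages, n_molecules: int = 150) -> RunConfig:
    RESULTS.mkdir(exist_ok=True)
    return RunConfig(conditions=CONDITIONS, n_molecules=n_molecules, stages=tuple(stages))
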