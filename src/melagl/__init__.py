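"""melagl: artificial-grammar learning of melody.

Finite-state melody generation, quantified Narmour implication-realization
scoring, one-to-one pitch-mapping optimization, graded ungrammatical
stimulus construction, MIDI rendering, a synthetic-participant simulator,
and the complete behavioral analysis pipeline.
"""

from importlib.resources import files as _files

from .grammar import (
    Grammar,
    GrammarError,
    PitchSequence,
    TerminalSequence,
    TonePair,
    TonePairAlphabet,
    build_grammatical_sets,
    enumerate_sequences,
    is_grammatical,
    load_grammar,
    realize_pitches,
    trace_pathway,
)
from .narmour import (
    FactorVector,
    IntervalPair,
    NarmourProfile,
    ScoringConfig,
    factor_scores,
    melody_profile,
    set_profile,
)
from .mapping import (
    Mapping,
    MappingScore,
    apply_mapping,
    candidate_mappings,
    default_target_pool,
    ranked_report,
    score_mappings,
    select_mapping,
)
from .stimuli import (
    Stimulus,
    StimulusSet,
    UNGRAM_COUNTS,
    assemble_test_set,
    gen_ungrammatical,
    length_match,
    read_manifest,
    write_manifest,
)
from .midi import RenderSpec, read_midi, render_midi
from .pipeline import AnalysisReport, analyze_dataset, build_feature_tables
from .simulate import (
    CohortConfig,
    default_baseline_config,
    default_experimental_config,
    recovery_report,
    simulate_cohort,
    simulate_two_cohorts,
)

__version__ = "0.1.0"


def fixture_grammar() -> Grammar:
    """Load the grammar fixture shipped with the package."""
    return load_grammar(_files(__name__).joinpath("data/fixture_grammar.yaml").read_text())
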