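import numpy as np
import pytest

from smtrack.colocalization import LinkRules, build_records, summarize_cell
from smtrack.presets import get_kinetic_preset
from smtrack.segmentation import bound_segments_from_record
from smtrack.synthetic import cohort_to_tracks, simulate_binding_cohort
from smtrack.tracking import LinkParams, filter_tracks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def run_binding_chain(preset_name, n_mrna, seed, *, window_s=300.0, dt_s=2.0,
                      frac_translating=1.0, rules=None, params=None,
                      min_bound_s=8.0, cell_id=0):
    """Trace-level detect->track->link->segment chain for one cell.

    Returns (records, bound segments, cell summary, cohort).
    """
    rules = rules or LinkRules.steady_state()
    params = params or LinkParams.steady_state()
    cohort = simulate_binding_cohort(get_kinetic_preset(preset_name), n_mrna,
                                     window_s, dt_s, seed=seed,
                                     frac_translating=frac_translating)
    tracks = cohort_to_tracks(cohort, seed=seed + 1)
    for chan in tracks:
        filter_tracks(tracks[chan], params, "steady_state", dt_s)
    records = build_records(tracks["mrna"], tracks["protein"],
                            tracks["tls"], rules, dt_s, cell_id=cell_id)
    segments = []
    for rec in records:
        segments.extend(bound_segments_from_record(rec, dt_s, min_bound_s))
    summary = summarize_cell(records, rules, cell_id=cell_id)
    return records, segments, summary, cohort
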