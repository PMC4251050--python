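"""Shared fixtures: the default synthetic benchmark, run once per session."""

from __future__ import annotations

import pytest

from eicqc import PeakRecord, PipelineConfig, generate_run
from eicqc.pipeline import peak_to_record, run_pipeline
from eicqc.synthetic_data import benchmark_spec


class Benchmark:
    """The default benchmark run plus pipeline results at several settings."""

    def __init__(self, seed: int):
        self.seed = seed
        self.spec = benchmark_spec(seed)
        self.run, self.truth = generate_run(self.spec)
        self.truth_records = [
            PeakRecord(eic_id=i, mz_apex=t.mz, rt_apex=t.rt_apex, source="truth")
            for i, t in enumerate(self.truth)
        ]
        self.config = PipelineConfig(seed=seed)
        self.filtered = run_pipeline(self.run, self.config)
        self.unfiltered = run_pipeline(self.run, self.config,
                                       eic_filter=False, peak_filter=False)
        self.peakfilter_only = run_pipeline(self.run, self.config,
                                            eic_filter=False, peak_filter=True)
        by_id = {e.eic_id: e for e in self.unfiltered.eics}
        self.unfiltered_records = [
            peak_to_record(by_id[p.eic_id], p) for p in self.unfiltered.all_peaks
        ]


@pytest.fixture(scope="session")
def bench() -> Benchmark:
    return Benchmark(seed=0)


@pytest.fixture(scope="session")
def bench_alt() -> Benchmark:
    return Benchmark(seed=1)
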