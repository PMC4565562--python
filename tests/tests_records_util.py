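"""Helpers for fabricating ErrorRecord tables in harness/report tests."""

import numpy as np

from grnfit import ErrorRecord


def synthetic_records(means, spread, n_rep, seed=0):
    """Records for one configuration with prescribed per-interval means."""
    rng = np.random.default_rng(seed)
    records = []
    for interval, mu in means.items():
        for rep in range(n_rep):
            e = float(np.clip(mu + rng.normal(0, spread), 1e-6, None))
            records.append(
                ErrorRecord(
                    system_id="A",
                    system_rate_law="hill",
                    system_omega_magnitude=1.0,
                    model_rate_law="hill",
                    model_omega_interval=interval,
                    replication_index=rep,
                    seed=rep,
                    training_error=e,
                    validation_error=e,
                )
            )
    return records
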