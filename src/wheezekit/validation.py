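"""End-to-end validation of the detector against simulator ground truth.

Runs the full recognition chain over an in-memory synthetic corpus and
scores the file-level decisions against the known labels.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import pandas as pd

from .classify import decide_file
from .config import RunConfig
from .metrics import ConfusionMatrix, confusion
from .synth import DEFAULT_PREVALENCE, iter_corpus


def corpus_confusion(
    n_files: int,
    seed: int,
    wheeze_prevalence: float = DEFAULT_PREVALENCE,
    snr_range: Tuple[float, float] = (5.0, 45.0),
    noise_rates: Optional[Dict[str, float]] = None,
    duration_s: float = 30.0,
    config: RunConfig = RunConfig(),
) -> Tuple[ConfusionMatrix, pd.DataFrame]:
    """Generate a corpus, run :func:`decide_file` on every recording, and
    return the confusion matrix against ground truth plus a per-file table."""
    rows = []
    for name, rec, truth in iter_corpus(
        n_files,
        wheeze_prevalence=wheeze_prevalence,
        noise_rates=noise_rates,
        seed=seed,
        duration_s=duration_s,
        snr_range=snr_range,
    ):
        decision = decide_file(rec, config)
        rows.append(
            {
                "file": name,
                "reference": truth.file_label,
                "predicted": decision.label,
                "n_true_events": len(truth.events),
                "n_detected_events": len(decision.events),
            }
        )
    table = pd.DataFrame(rows)
    return confusion(table["reference"], table["predicted"]), table
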