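"""End-to-end analysis: filter -> detect -> jitter -> evolution -> transitions.

:func:`run_pipeline` takes a recording (or a simulation config), applies the
configured preprocessing presets, detects seizures per channel, computes the
pairwise jitter matrix, the windowed jitter trace and the called state
transitions, and writes everything to an output directory:

``events.csv``
    Canonical event table (seizures + spikes).
``jitter_matrix.csv``
    Long-format pairwise jitter (seizure_i, seizure_j, jitter_pct, n_interval).
``trace.csv``
    Windowed jitter trace.
``transitions.csv``
    Called transitions (onset_s, offset_s, peak_jitter_pct).
``report.json``
    Summary: seizure count, duration/interval Fano factors, transition
    count, package version and the fully resolved configuration.

All outputs are deterministic for deterministic inputs. If any stage fails,
partial outputs are removed and the stage name is reported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import detect_params_from, resolve_config
from .detect import detect_seizures, seizures_to_table
from .dynamics import detect_transitions, fano, windowed_jitter
from .errors import SzjitterError
from .io import Recording, write_events
from .jitter import jitter
from .preprocess import apply_filter

__all__ = ["run_pipeline", "pairwise_long"]

_OUTPUTS = ("events.csv", "jitter_matrix.csv", "trace.csv",
            "transitions.csv", "report.json")


class PipelineStageError(SzjitterError):
    """A pipeline stage failed; carries the stage name and resolved config."""

    def __init__(self, stage: str, config: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}\n"
                         f"resolved config: {config}")
        self.stage = stage
        self.config = config


def pairwise_long(seizures, pairing: str = "signed") -> pd.DataFrame:
    """Long-format pairwise jitter over a seizure list."""
    rows = []
    for i in range(len(seizures)):
        for j in range(i + 1, len(seizures)):
            a, b = seizures[i], seizures[j]
            if len(a.spikes) < 2 or len(b.spikes) < 2:
                rows.append(dict(seizure_i=i, seizure_j=j,
                                 jitter_pct=np.nan, n_interval=0))
                continue
            res = jitter(a.spikes, b.spikes, pairing=pairing)
            rows.append(dict(seizure_i=i, seizure_j=j,
                             jitter_pct=res.jitter_pct,
                             n_interval=res.n_interval))
    return pd.DataFrame(rows, columns=["seizure_i", "seizure_j",
                                       "jitter_pct", "n_interval"])


def run_pipeline(rec: Recording, config: dict | None, outdir) -> dict:
    """Run the full chain on a recording and write outputs to ``outdir``.

    Returns the report dict. See the module docstring for the files written.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(rec, cfg, outdir)
    except Exception:
        for name in _OUTPUTS:  # no partial results on failure
            (outdir / name).unlink(missing_ok=True)
        raise


def _run(rec: Recording, cfg: dict, outdir: Path) -> dict:
    stage = "preprocess"
    try:
        for preset_name in cfg["preprocess"]["presets"]:
            rec = apply_filter(rec, preset_name)

        stage = "detect"
        params = detect_params_from(cfg)
        seizures = []
        for channel in rec.channel_ids:
            seizures.extend(detect_seizures(rec, params, channel=channel))
        seizures.sort(key=lambda s: s.start_s)
        write_events(seizures_to_table(seizures), outdir / "events.csv")

        stage = "jitter"
        pairwise_long(seizures, cfg["jitter"]["pairing"]).to_csv(
            outdir / "jitter_matrix.csv", index=False, float_format="%.9g"
        )

        stage = "dynamics"
        transitions = []
        if len(seizures) >= 2:
            trace = windowed_jitter(
                seizures, cfg["dynamics"]["window_s"], cfg["dynamics"]["step_s"]
            )
            trace.to_frame().to_csv(outdir / "trace.csv", index=False,
                                    float_format="%.9g")
            if np.sum(~np.isnan(trace.jitter_pct)) >= 3:
                transitions = detect_transitions(trace, cfg["dynamics"]["k_sd"])
        else:
            pd.DataFrame(
                columns=["window_start_s", "jitter_pct", "n_seizures_in_window"]
            ).to_csv(outdir / "trace.csv", index=False)
        pd.DataFrame(
            [dict(onset_s=t.onset_s, offset_s=t.offset_s,
                  peak_jitter_pct=t.peak_jitter_pct) for t in transitions],
            columns=["onset_s", "offset_s", "peak_jitter_pct"],
        ).to_csv(outdir / "transitions.csv", index=False, float_format="%.9g")

        stage = "report"
        durations = [s.duration_s for s in seizures]
        intervals = list(np.diff([s.start_s for s in seizures]))
        report = {
            "version": __version__,
            "n_seizures": len(seizures),
            "fano_duration": fano(durations) if len(durations) >= 2 else None,
            "fano_interval": fano(intervals) if len(intervals) >= 2 else None,
            "n_transitions": len(transitions),
            "config": cfg,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        return report
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, cfg, exc) from exc
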