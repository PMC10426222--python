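"""End-to-end convenience pipeline over the library modules.

Chains cohort generation (or loading), denoising + gating, corroboration
screening + windowing, feature extraction + normalization.  Mostly a thin
wrapper so scripts, tests, and the CLI share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import ppg_denoise, synthetic_cohort, tsfeatures, windows
from .synthetic_cohort import GeneratorConfig, SessionRecording
from .tsfeatures import FeatureBankConfig, FeatureMatrix


@dataclass
class PipelineResult:
    sessions: list[SessionRecording]
    windows_by_session: dict[str, list]
    matrix_raw: FeatureMatrix
    matrix: FeatureMatrix  # max-min normalized


def run_pipeline(
    sessions: list[SessionRecording] | None = None,
    generator_config: GeneratorConfig | None = None,
    denoise: bool = True,
    filter_config: ppg_denoise.FilterConfig | None = None,
    window_config: windows.WindowingConfig | None = None,
    bank_config: FeatureBankConfig | None = None,
    apply_exclusions: bool = True,
) -> PipelineResult:
    """Run generation -> denoise/gate -> window -> features -> normalize.

    Pass either ``sessions`` (pre-loaded recordings) or ``generator_config``.
    With ``denoise=False`` the quality gate is skipped and every in-section
    window is kept (appropriate when recordings carry no motion artifacts).
    """
    if sessions is None:
        if generator_config is None:
            raise ValueError("provide sessions or a generator_config")
        sessions = synthetic_cohort.generate_cohort(generator_config)
    fcfg = filter_config or ppg_denoise.FilterConfig()
    wcfg = window_config or windows.WindowingConfig()
    bcfg = bank_config or FeatureBankConfig()

    by_session: dict[str, list] = {}
    for s in sessions:
        gate = None
        if denoise:
            _, gate = ppg_denoise.denoise_session(s, fcfg)
        by_session[s.session_id] = windows.window_session(s, gate, wcfg)
    if apply_exclusions:
        by_session = windows.exclusion_filter(by_session)
    all_windows = [w for ws in by_session.values() for w in ws]
    matrix_raw = tsfeatures.build_matrix(all_windows, bcfg)
    matrix = tsfeatures.maxmin_normalize(matrix_raw)
    return PipelineResult(sessions, by_session, matrix_raw, matrix)
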