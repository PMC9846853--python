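"""End-to-end analysis as a model/results pair.

:class:`VoicePatternAnalysis` bundles the data of a voice-localizer
style experiment — one activity pattern per participant, ROI and
hemisphere, plus the stimulus catalog — and :meth:`fit` runs the
complete multivariate analysis for every requested standardization
scheme: balanced two-fold decoding of vocal vs. non-vocal events with a
dummy-classification null, and RSA of the group RDMs against the
categorical models with Bonferroni-corrected within-vs-between planned
comparisons. The returned :class:`VoicePatternResults` carries tidy
tables, MDS coordinates, provenance, and a ``summary()``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .decoding import bootstrap_null_threshold, decode_vocal_vs_nonvocal
from .errors import InvalidArgumentError
from .patterns import ActivityPattern, standardize
from .rsa import (
    RDM,
    compute_rdm,
    correlate_rdms,
    enumerate_planned_comparisons,
    make_model_rdm,
    mds_embed,
    within_between_test,
    MODEL_NAMES,
    _MODEL_GROUPS,
)
from .simulate import GenerativeConfig, generate_beta_patterns
from .stimuli import StimulusSet, generate_stimulus_set


@dataclass(frozen=True)
class AnalysisConfig:
    """Serializable description of a full analysis run.

    ROI effect profiles: the voice-selective ROI ("TVA") carries the
    vocal pattern and the speech gain of :class:`GenerativeConfig`; the
    control ROI ("A1") is noise-only (no categorical structure), so the
    analysis should find signal in one and not the other.
    """

    n_participants: int = 5
    n_per_subcategory: int = 12
    rois: tuple[str, ...] = ("A1", "TVA")
    hemispheres: tuple[str, ...] = ("left", "right")
    standardizations: tuple[str, ...] = ("along_stimuli", "along_voxels")
    vocal_subsets: tuple[str, ...] = ("speech", "nonspeech_vocal")
    models: tuple[str, ...] = MODEL_NAMES
    n_voxels: int = 57
    vocal_effect: float = 0.6
    speech_gain: float = 1.0
    noise_sd: float = 0.4
    selectivity_fraction: float = 0.5
    n_runs: int = 2
    decode_n_iter: int = 100_000
    decode_quantile: float = 0.95
    rsa_n_iter: int = 10_000
    rsa_alpha: float = 0.01
    rsa_resample: str = "conditions"
    seed: int = 0
    output_dir: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: AnalysisConfig) -> list[str]:
    """Collect all configuration problems without side effects."""
    issues = []
    if config.n_participants < 1:
        issues.append("n_participants must be >= 1")
    if config.n_per_subcategory < 1:
        issues.append("n_per_subcategory must be >= 1")
    if not (0 < config.decode_quantile < 1):
        issues.append("decode_quantile must be in (0, 1)")
    if config.decode_n_iter < 1:
        issues.append("decode_n_iter must be >= 1")
    if config.rsa_n_iter < 1:
        issues.append("rsa_n_iter must be >= 1")
    if not config.models:
        issues.append("models list is empty")
    for m in config.models:
        if m not in MODEL_NAMES:
            issues.append(f"unknown model {m!r}")
    for s in config.standardizations:
        if s not in ("none", "along_stimuli", "along_voxels"):
            issues.append(f"unknown standardization {s!r}")
    if config.n_voxels < 2:
        issues.append("n_voxels must be >= 2")
    if config.noise_sd < 0:
        issues.append("noise_sd must be >= 0")
    if config.n_runs < 2:
        issues.append("two-fold decoding needs n_runs >= 2")
    return issues


def _derived_seed(master: int, *tags) -> int:
    """Stable 31-bit stream seed for a named pipeline stage."""
    h = hashlib.sha256(("|".join(map(str, (master,) + tags))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class VoicePatternAnalysis:
    """The full multivariate analysis, built from data.

    Parameters
    ----------
    patterns : mapping ``(participant_id, roi, hemisphere) -> ActivityPattern``
        Unstandardized event-level patterns (|stimuli| x n_runs rows).
    stimulus_set : the catalog the rows refer to.
    config : analysis parameters; seeds make ``fit`` deterministic.
    """

    def __init__(
        self,
        patterns: dict[tuple[str, str, str], ActivityPattern],
        stimulus_set: StimulusSet,
        config: AnalysisConfig = AnalysisConfig(),
    ):
        issues = validate_config(config)
        if issues:
            raise InvalidArgumentError("invalid config: " + "; ".join(issues))
        if not patterns:
            raise InvalidArgumentError("no activity patterns supplied")
        self.patterns = patterns
        self.stimulus_set = stimulus_set
        self.config = config

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_synthetic(cls, config: AnalysisConfig = AnalysisConfig()) -> "VoicePatternAnalysis":
        """Simulate every participant/ROI/hemisphere pattern.

        The voice-selective ROI gets the configured vocal pattern and
        speech gain; the control ROI is noise-only.
        """
        issues = validate_config(config)
        if issues:
            raise InvalidArgumentError("invalid config: " + "; ".join(issues))
        stim = generate_stimulus_set(
            config.n_per_subcategory, seed=_derived_seed(config.seed, "stimuli")
        )
        patterns = {}
        for p in range(config.n_participants):
            pid = f"sub-{p + 1:02d}"
            for roi in config.rois:
                voice_selective = roi.upper().startswith("TVA")
                for hemi in config.hemispheres:
                    gen = GenerativeConfig(
                        n_voxels=config.n_voxels,
                        vocal_effect=config.vocal_effect if voice_selective else 0.0,
                        speech_gain=config.speech_gain if voice_selective else 0.0,
                        noise_sd=config.noise_sd,
                        selectivity_fraction=config.selectivity_fraction,
                        n_runs=config.n_runs,
                        seed=_derived_seed(config.seed, "beta", pid, roi, hemi),
                    )
                    patterns[(pid, roi, hemi)] = generate_beta_patterns(
                        stim, gen, participant_id=pid
                    )
        return cls(patterns, stim, config)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        stimulus_set: StimulusSet,
        config: AnalysisConfig = AnalysisConfig(),
    ) -> "VoicePatternAnalysis":
        """Build from a long-format table with columns ``participant_id``,
        ``roi``, ``hemisphere``, ``stimulus_id``, ``run`` and voxel columns
        (every remaining numeric column is a voxel)."""
        key_cols = ["participant_id", "roi", "hemisphere", "stimulus_id", "run"]
        missing = [c for c in key_cols if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"missing columns: {missing}")
        voxel_cols = [c for c in df.columns if c not in key_cols]
        patterns = {}
        for (pid, roi, hemi), grp in df.groupby(
            ["participant_id", "roi", "hemisphere"], sort=True
        ):
            patterns[(str(pid), str(roi), str(hemi))] = ActivityPattern(
                values=grp[voxel_cols].to_numpy(float),
                row_labels=grp["stimulus_id"].astype(str).tolist(),
                run_labels=grp["run"].to_numpy(),
                participant_id=str(pid),
            )
        return cls(patterns, stimulus_set, config)

    # ----------------------------------------------------------------- fitting
    def fit(self) -> "VoicePatternResults":
        cfg = self.config
        # decoding -----------------------------------------------------------
        n_balanced_events = 24 * cfg.n_runs
        null = bootstrap_null_threshold(
            n_events=n_balanced_events,
            n_iter=cfg.decode_n_iter,
            quantile=cfg.decode_quantile,
            seed=_derived_seed(cfg.seed, "null"),
        )
        decoding_rows = []
        for (pid, roi, hemi), pattern in sorted(self.patterns.items()):
            for subset in cfg.vocal_subsets:
                for scheme in cfg.standardizations:
                    res = decode_vocal_vs_nonvocal(
                        pattern,
                        self.stimulus_set,
                        vocal_subset=subset,
                        scheme=scheme,
                        seed=_derived_seed(cfg.seed, "balance", subset),
                        roi_name=f"{roi}-{hemi}",
                    ).attach_null(null.threshold, null.n_iter, null.quantile)
                    decoding_rows.append(
                        {
                            "participant_id": pid,
                            "roi": roi,
                            "hemisphere": hemi,
                            "vocal_subset": subset,
                            "standardization": scheme,
                            "fold1": res.fold_accuracies[0],
                            "fold2": res.fold_accuracies[1],
                            "mean_accuracy": res.mean_accuracy,
                            "null_threshold": res.null_threshold,
                            "significant": res.significant,
                        }
                    )
        decoding_table = pd.DataFrame(decoding_rows)

        # RSA ----------------------------------------------------------------
        group_rdms: dict[tuple[str, str, str], RDM] = {}
        for roi in cfg.rois:
            for hemi in cfg.hemispheres:
                for scheme in cfg.standardizations:
                    mats = []
                    for p in sorted({k[0] for k in self.patterns}):
                        pat = self.patterns[(p, roi, hemi)]
                        mats.append(compute_rdm(standardize(pat, scheme)).matrix)
                    rdm = RDM(
                        condition_labels=self.stimulus_set.ids,
                        matrix=np.mean(mats, axis=0),
                        metric_tag="euclidean",
                        name=f"{roi}-{hemi}:{scheme}",
                    )
                    group_rdms[(roi, hemi, scheme)] = rdm

        model_rdms = {m: make_model_rdm(self.stimulus_set, m) for m in cfg.models}
        corr_rows = [
            {
                "roi": roi,
                "hemisphere": hemi,
                "standardization": scheme,
                "model": m,
                "spearman_rho": correlate_rdms(rdm, model_rdms[m]).spearman_rho,
            }
            for (roi, hemi, scheme), rdm in group_rdms.items()
            for m in cfg.models
        ]
        rdm_correlations = pd.DataFrame(corr_rows)

        specs, m_factor = enumerate_planned_comparisons(
            cfg.rois, cfg.standardizations, cfg.models, cfg.hemispheres
        )
        planned_rows = []
        for spec in specs:
            rdm = group_rdms[(spec["roi_name"], spec["hemisphere"], spec["standardization"])]
            partition = [
                _MODEL_GROUPS[spec["model_name"]](s) for s in self.stimulus_set
            ]
            res = within_between_test(
                rdm,
                partition,
                n_iter=cfg.rsa_n_iter,
                seed=_derived_seed(cfg.seed, "boot", *spec.values()),
                resample=cfg.rsa_resample,
                **spec,
            ).correct(m_factor)
            planned_rows.append(
                {
                    "roi": res.roi_name,
                    "hemisphere": res.hemisphere,
                    "standardization": res.standardization,
                    "model": res.model_name,
                    "t_stat": res.t_stat,
                    "p_boot": res.p_boot,
                    "p_corrected": res.p_corrected,
                    "m": res.m,
                    "significant": res.p_corrected < cfg.rsa_alpha,
                }
            )
        planned_comparisons = pd.DataFrame(planned_rows)

        # MDS over brain + model RDMs per standardization --------------------
        mds_rows = []
        for scheme in cfg.standardizations:
            rdms = [
                group_rdms[(roi, hemi, scheme)]
                for roi in cfg.rois
                for hemi in cfg.hemispheres
            ] + [model_rdms[m] for m in cfg.models]
            coords = mds_embed(rdms)
            for rdm, (x, y) in zip(rdms, coords):
                mds_rows.append(
                    {"standardization": scheme, "rdm": rdm.name, "x": x, "y": y}
                )
        mds_coordinates = pd.DataFrame(mds_rows)

        return VoicePatternResults(
            model=self,
            decoding_table=decoding_table,
            rdm_correlations=rdm_correlations,
            planned_comparisons=planned_comparisons,
            mds_coordinates=mds_coordinates,
            group_rdms=group_rdms,
            model_rdms=model_rdms,
            null_threshold=null.threshold,
            provenance={
                "config": cfg.to_dict(),
                "config_hash": cfg.content_hash(),
                "seed": cfg.seed,
                "bonferroni_m": m_factor,
                "null": {"n_iter": null.n_iter, "quantile": null.quantile,
                         "mean": null.mean, "threshold": null.threshold},
            },
        )


@dataclass
class VoicePatternResults:
    """Fitted tables, diagnostics and provenance of one analysis run."""

    model: VoicePatternAnalysis
    decoding_table: pd.DataFrame
    rdm_correlations: pd.DataFrame
    planned_comparisons: pd.DataFrame
    mds_coordinates: pd.DataFrame
    group_rdms: dict
    model_rdms: dict
    null_threshold: float
    provenance: dict = field(default_factory=dict)

    def mean_accuracies(self) -> pd.DataFrame:
        """Group-mean decoding accuracy per ROI x subset x standardization."""
        return (
            self.decoding_table.groupby(["roi", "vocal_subset", "standardization"])[
                "mean_accuracy"
            ]
            .mean()
            .reset_index()
        )

    def summary(self) -> str:
        lines = [
            "Voice-region multivariate pattern analysis",
            "=" * 58,
            f"participants: {self.model.config.n_participants}   "
            f"stimuli: {len(self.model.stimulus_set)}   "
            f"voxels/ROI: {self.model.config.n_voxels}",
            f"decoding null threshold (q={self.provenance['null']['quantile']}): "
            f"{self.null_threshold:.3f}",
            "",
            "Mean decoding accuracy (vocal vs non-vocal):",
            self.mean_accuracies().to_string(index=False, float_format="%.3f"),
            "",
            "Group RDM vs model RDM (Spearman rho):",
            self.rdm_correlations.to_string(index=False, float_format="%.3f"),
            "",
            f"Planned within-vs-between comparisons "
            f"(Bonferroni m={self.provenance['bonferroni_m']}):",
            self.planned_comparisons.to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)

    def save(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.decoding_table.to_csv(out / "decoding.tsv", sep="\t", index=False)
        self.rdm_correlations.to_csv(out / "rdm_correlations.tsv", sep="\t", index=False)
        self.planned_comparisons.to_csv(
            out / "planned_comparisons.tsv", sep="\t", index=False
        )
        self.mds_coordinates.to_csv(out / "mds.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(self.provenance, indent=1))
        for key, rdm in self.group_rdms.items():
            rdm.to_tsv(out / ("rdm_" + "_".join(key) + ".tsv"))


def run_analysis(config: AnalysisConfig) -> VoicePatternResults:
    """Simulate (or load), fit, and optionally write the report."""
    results = VoicePatternAnalysis.from_synthetic(config).fit()
    if config.output_dir:
        results.save(config.output_dir)
    return results
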