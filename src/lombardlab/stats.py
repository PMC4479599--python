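"""Trial-level aggregation and the repeated-measures ANCOVA.

The unit of analysis is the trial mean: per-call measurements are averaged
within each (subject, trial) cell — source levels in the linear pascal
domain, everything else arithmetically.  Each response is then modeled as

    response ~ noise_level + bandwidth + noise_level:bandwidth

with noise level a continuous covariate (dB re 20 μPa; control trials enter
at the measured ambient level), bandwidth a two-level factor (control trials
inherit the bandwidth class of their session's treatment trial), and subject
identity as a random intercept.  Per-term F statistics are Wald tests on the
REML fixed effects with containment-style denominator degrees of freedom
(``n − rank[fixed design + subject indicators]``), which for a complete
3-subject × 12-trial design gives F(1, 30) for every term; incomplete
designs (subjects missing a call type in some trials) yield correspondingly
smaller denominator df.  Missing cells are omitted, never imputed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .acoustics import CallMeasurements
from .audio_io import TrialRecord, P_REF
from .stimuli import NoiseTreatment, AMBIENT_DB, treatment_bank

#: canonical response name -> source column in a calls table (measurement
#: output or generator truth)
RESPONSE_SOURCES = {
    "source_level": ("source_level_db", "level_db"),
    "source_level_whistles": ("whistle_level_db",),
    "duration": ("duration_s",),
    "duration_whistles": ("whistle_duration_s",),
    "peak_f0": ("f0_peak_hz",),
    "min_f0": ("f0_min_hz",),
    "peak_freq": ("peak_freq_hz",),
    "peak_freq_whistles": ("whistle_peak_hz",),
    "max_freq": ("max_freq_hz",),
    "min_freq": ("min_freq_hz",),
    "tilt": ("tilt_ratio",),
}

LEVEL_RESPONSES = frozenset({"source_level", "source_level_whistles"})
FREQUENCY_RESPONSES = frozenset(
    {"peak_f0", "min_f0", "peak_freq", "peak_freq_whistles", "max_freq", "min_freq"})

#: Report row order: response grid for the two call types.
REPORT_ROWS = [
    ("CLC", "source_level", "Source level (whole call)"),
    ("CLC", "source_level_whistles", "Source level (whistles)"),
    ("CLC", "duration", "Duration (whole call)"),
    ("CLC", "duration_whistles", "Duration (whistles)"),
    ("CLC", "peak_f0", "Peak fundamental frequency"),
    ("CLC", "min_f0", "Minimum fundamental frequency"),
    ("CLC", "peak_freq", "Peak frequency (whole call)"),
    ("CLC", "peak_freq_whistles", "Peak frequency (whistles)"),
    ("CLC", "tilt", "Spectral tilt"),
    ("chirp", "source_level", "Source level"),
    ("chirp", "duration", "Duration"),
    ("chirp", "peak_freq", "Peak frequency"),
    ("chirp", "max_freq", "Maximum frequency"),
    ("chirp", "min_freq", "Minimum frequency"),
    ("chirp", "tilt", "Spectral tilt"),
]

TERMS = ("noise_level", "bandwidth", "interaction")


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable ANCOVA designs."""


@dataclasses.dataclass
class TermTest:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclasses.dataclass
class AncovaResult:
    """Per-term F tests for one response, plus the noise-level slope."""

    call_type: str
    response: str
    terms: dict[str, TermTest]
    n_obs: int
    noise_slope: float
    noise_slope_se: float


# ---------------------------------------------------------------------------
# Aggregation


def measurements_to_frame(per_trial: dict[str, list[CallMeasurements]]) -> pd.DataFrame:
    """Flatten measure_call output into a calls table keyed by wav_path."""
    rows = []
    for wav, measures in per_trial.items():
        for m in measures:
            rows.append({
                "wav_path": wav, "call_id": m.call_id, "call_type": m.call_type,
                "source_level_db": m.source_level_db,
                "whistle_level_db": m.whistle_level_db,
                "duration_s": m.duration_s,
                "whistle_duration_s": (float(np.mean(m.whistle_durations_s))
                                       if m.whistle_durations_s else None),
                "f0_min_hz": m.f0_min_hz, "f0_peak_hz": m.f0_peak_hz,
                "peak_freq_hz": m.peak_freq_hz, "whistle_peak_hz": m.whistle_peak_hz,
                "max_freq_hz": m.max_freq_hz, "min_freq_hz": m.min_freq_hz,
                "tilt_ratio": m.tilt_ratio,
                "flags": ";".join(m.flags),
            })
    return pd.DataFrame(rows)


def _canonical_calls(calls: pd.DataFrame) -> pd.DataFrame:
    out = calls.copy()
    for name, sources in RESPONSE_SOURCES.items():
        if name in out.columns:
            continue
        for src in sources:
            if src in out.columns:
                out[name] = out[src]
                break
        else:
            out[name] = np.nan
    return out


def _db_mean(values: pd.Series) -> float:
    """Mean of dB levels taken in the linear pascal domain, returned in dB."""
    v = values.dropna()
    if v.empty:
        return np.nan
    pa = P_REF * 10.0 ** (v.to_numpy() / 20.0)
    return float(20.0 * np.log10(np.mean(pa) / P_REF))


def aggregate(calls: pd.DataFrame, manifest: Optional[list[TrialRecord]] = None,
              bank: Optional[list[NoiseTreatment]] = None,
              ambient_db: float = AMBIENT_DB,
              trial_noise_db: Optional[dict[str, float]] = None) -> pd.DataFrame:
    """Aggregate per-call rows into one row per (subject, trial, call type).

    ``calls`` is either a measurement table keyed by ``wav_path`` (requires
    ``manifest``) or a generator truth table that already carries trial
    metadata.  Control rows receive the measured ambient level when
    ``trial_noise_db`` provides one, otherwise ``ambient_db``; their
    bandwidth class is that of the session's treatment trial.  Calls whose
    wav_path is missing from the manifest are an error.
    """
    calls = _canonical_calls(calls)

    if manifest is not None:
        bank = bank if bank is not None else treatment_bank()
        by_name = {t.name: t for t in bank}
        meta = {}
        session_bw = {}
        for r in manifest:
            if r.trial_type == "treatment":
                session_bw[(r.subject, r.session)] = by_name[r.treatment].bandwidth_class
        for r in manifest:
            if r.trial_type == "treatment":
                bw = by_name[r.treatment].bandwidth_class
                noise = by_name[r.treatment].target_db
            else:
                bw = session_bw.get((r.subject, r.session), "narrow")
                noise = ambient_db
            if trial_noise_db and r.wav_path in trial_noise_db:
                noise = trial_noise_db[r.wav_path]
            meta[r.wav_path] = {
                "subject": r.subject, "session": r.session, "trial_id": r.wav_path,
                "trial_type": r.trial_type,
                "treatment": r.treatment if r.treatment else "none",
                "bandwidth_class": bw, "noise_db": noise,
            }
        orphans = sorted(set(calls["wav_path"]) - set(meta))
        if orphans:
            raise DesignError(f"calls reference trials absent from the manifest: {orphans}")
        meta_df = pd.DataFrame.from_dict(meta, orient="index")
        meta_df.index.name = "wav_path"
        calls = calls.merge(meta_df.reset_index(), on="wav_path", how="left")

    keys = ["subject", "session", "trial_id", "trial_type", "treatment",
            "bandwidth_class", "noise_db", "call_type"]
    rows = []
    for key_vals, grp in calls.groupby(keys, sort=True):
        row = dict(zip(keys, key_vals))
        row["n_calls"] = len(grp)
        for resp in RESPONSE_SOURCES:
            row[resp] = _db_mean(grp[resp]) if resp in LEVEL_RESPONSES \
                else (float(grp[resp].mean()) if grp[resp].notna().any() else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANCOVA


def _containment_df(data: pd.DataFrame, exog: np.ndarray) -> int:
    subj = pd.get_dummies(data["subject"]).to_numpy(dtype=float)
    aug = np.hstack([exog, subj])
    return int(data.shape[0] - np.linalg.matrix_rank(aug))


def fit_ancova(table: pd.DataFrame, response: str, call_type: Optional[str] = None) -> AncovaResult:
    """Fit the mixed ANCOVA for one response and return per-term F tests.

    The model is ``response ~ noise_db * C(bandwidth_class, Sum)`` with a
    random subject intercept, fit by REML; each term is a 1-df Wald F test
    against the containment denominator df.  Requires at least two subjects
    and two distinct noise levels; a rank-deficient fixed design raises
    :class:`DesignError` naming the aliased term.
    """
    data = table.copy()
    if call_type is not None:
        data = data[data["call_type"] == call_type]
    data = data.dropna(subset=[response, "noise_db", "bandwidth_class", "subject"])
    if data["subject"].nunique() < 2:
        raise DesignError("need at least two subjects")
    if data["noise_db"].nunique() < 2:
        raise DesignError("need at least two distinct noise levels")

    # fit on the standardized response for numerical stability; F and p are
    # invariant under the affine rescaling, the slope is scaled back below
    scale = float(data[response].std(ddof=1))
    if not np.isfinite(scale) or scale == 0:
        scale = 1.0
    data = data.assign(_resp=(data[response] - data[response].mean()) / scale)

    formula = "_resp ~ noise_db * C(bandwidth_class, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject"])
        exog = model.exog
        names = list(model.exog_names)
        term_cols = _term_columns(names)
        for term, cols in term_cols.items():
            reduced = np.delete(exog, cols, axis=1)
            if np.linalg.matrix_rank(exog) <= np.linalg.matrix_rank(reduced):
                raise DesignError(f"design is rank deficient: term '{term}' is aliased")
        result = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                result = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.all(np.isfinite(result.fe_params)):
                break
        if result is None or not np.all(np.isfinite(np.asarray(result.fe_params))):
            raise DesignError(f"mixed-model fit failed for response '{response}'")

    k = len(names)
    fe = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[:k, :k]
    df_den = _containment_df(data, exog)

    terms: dict[str, TermTest] = {}
    for term, cols in term_cols.items():
        L = np.zeros((len(cols), k))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        lb = L @ fe
        lvl = L @ cov @ L.T
        F = float(lb @ np.linalg.solve(lvl, lb) / len(cols))
        p = float(sps.f.sf(F, len(cols), df_den))
        terms[term] = TermTest(F, len(cols), df_den, p)

    i_nl = names.index("noise_db")
    return AncovaResult(
        call_type=call_type or str(data["call_type"].iloc[0]) if "call_type" in data else "",
        response=response, terms=terms, n_obs=int(data.shape[0]),
        noise_slope=float(fe[i_nl]) * scale,
        noise_slope_se=float(np.sqrt(cov[i_nl, i_nl])) * scale,
    )


def _term_columns(names: list[str]) -> dict[str, list[int]]:
    cols = {"noise_level": [], "bandwidth": [], "interaction": []}
    for i, name in enumerate(names):
        if name == "Intercept":
            continue
        if ":" in name:
            cols["interaction"].append(i)
        elif name.startswith("noise_db"):
            cols["noise_level"].append(i)
        elif name.startswith("C(bandwidth_class"):
            cols["bandwidth"].append(i)
    missing = [t for t, c in cols.items() if not c]
    if missing:
        raise DesignError(f"term(s) {missing} aliased or absent from the design {names}")
    return cols


# ---------------------------------------------------------------------------
# Tables


def delta_table(summaries: pd.DataFrame, response: str,
                call_type: Optional[str] = None) -> pd.DataFrame:
    """Per-(subject, treatment) control value, treatment value and Δ.

    Pairing is by session: the control value for a treatment is the mean of
    the subject's control trials in the sessions where that treatment was
    presented (falling back to the subject's overall control mean when no
    session column is available).  Δ = treatment − control; frequency
    responses are rounded to integer Hz.  Missing pairs yield missing Δ.
    """
    df = summaries
    if call_type is not None:
        df = df[df["call_type"] == call_type]
    has_session = "session" in df.columns
    rows = []
    as_int = response in FREQUENCY_RESPONSES
    for subject, grp in df.groupby("subject", sort=True):
        controls = grp[grp["trial_type"] == "control"]
        overall = controls[response].dropna()
        overall_val = float(overall.mean()) if not overall.empty else np.nan
        for treatment, tgrp in grp[grp["trial_type"] == "treatment"].groupby("treatment", sort=True):
            if has_session:
                paired = controls[controls["session"].isin(tgrp["session"])][response].dropna()
                ctrl_val = float(paired.mean()) if not paired.empty else overall_val
            else:
                ctrl_val = overall_val
            tv = tgrp[response].dropna()
            t_val = float(tv.mean()) if not tv.empty else np.nan
            delta = t_val - ctrl_val
            if as_int:
                ctrl_out = round(ctrl_val) if np.isfinite(ctrl_val) else np.nan
                t_out = round(t_val) if np.isfinite(t_val) else np.nan
                delta = t_out - ctrl_out if np.isfinite(delta) else np.nan
            else:
                ctrl_out, t_out = ctrl_val, t_val
            rows.append({"subject": subject, "treatment": treatment,
                         "control": ctrl_out, "treatment_value": t_out, "delta": delta})
    return pd.DataFrame(rows, columns=["subject", "treatment", "control", "treatment_value", "delta"])


def report(results: list[AncovaResult]) -> tuple[pd.DataFrame, str]:
    """Format fitted ANCOVA results as a fixed-order grid (CSV frame + text).

    Rows follow the canonical response order for each call type; p values are
    printed to two decimals with a significance flag at p ≤ 0.05.  Identical
    inputs give byte-identical output.
    """
    by_key = {(r.call_type, r.response): r for r in results}
    rows = []
    lines = [f"{'Response':<34} " + " ".join(f"{t:>22}" for t in ("NL", "BW", "NL*BW"))]
    for call_type, response, label in REPORT_ROWS:
        r = by_key.get((call_type, response))
        if r is None:
            continue
        row = {"call_type": call_type, "response": response, "label": label, "n_obs": r.n_obs}
        cells = []
        for term in TERMS:
            t = r.terms[term]
            row[f"{term}_F"] = round(t.F, 2)
            row[f"{term}_df_num"] = t.df_num
            row[f"{term}_df_den"] = t.df_den
            row[f"{term}_p"] = round(t.p, 4)
            row[f"{term}_significant"] = bool(t.p <= 0.05)
            star = "*" if t.p <= 0.05 else " "
            cells.append(f"F{t.df_num},{t.df_den}={t.F:7.2f} p={t.p:4.2f}{star}")
        rows.append(row)
        lines.append(f"{call_type + ': ' + label:<34} " + " ".join(f"{c:>22}" for c in cells))
    return pd.DataFrame(rows), "\n".join(lines) + "\n"
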