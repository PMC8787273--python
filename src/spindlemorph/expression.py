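"""Relative expression quantification: primer QC, ddCt fold changes,
proportional Myh composition, western-blot adjusted relative density and
viability fold change.

Gene expression follows the dCt / 2^-ddCt convention: triplicate Ct values
are averaged; dCt is the gene's mean Ct minus the reference gene's
(Csnk2a2) on the same sample; ddCt subtracts the mean control dCt of the
same plate; fold change is 2^-ddCt.  Myh isoform composition linearises
each gene as 2^-dCt and expresses it as a percentage of the summed
linearised Myh signal per sample -- a share, which the reference gene
cancels out of.
"""

from __future__ import annotations

import warnings
from io import StringIO

import numpy as np
import pandas as pd

CT_COLUMNS = ["ct1", "ct2", "ct3"]
REFERENCE_GENE = "Csnk2a2"

#: Primer pairs used for the mRNA panel: gene, amplification efficiency (%)
#: and accession of the target transcript.  Per-gene r-squared and melt-curve
#: values are not tabulated (the study's inclusion rule implies both passed),
#: so those QC rules are recorded as not evaluated for this table.
_PRIMER_CSV = """gene,efficiency,accession
Myh1,102.3,NM_030679.2
Myh2,107.3,NM_001039545.2
Myh3,92.4,NM_001099635.1
Myh4,102.4,NM_010855.3
Myh6,101.3,NM_001164171.1
Myh7,90.2,NM_080728.3
Myh8,103.7,NM_177369.3
Myh13,97.4,NM_001081250.2
Myh7b/14,106.6,NM_001085378.2
Csnk2a2,97.9,NM_009974.3
Myf5,96.0,NM_008656.5
Myod1,98.1,NM_010266.2
Myog,100.2,NM_031189.2
Egr3,106.5,NM_018781.4
Gdnf,111.7,NM_010275.3
Prph,92.0,NM_013639.2
Sstr2,110.5,NM_001042606.3
Etv4,92.9,NM_001316365.1
"""


def reference_primer_table() -> pd.DataFrame:
    """The packaged primer panel (18 pairs) with printed efficiencies."""
    return pd.read_csv(StringIO(_PRIMER_CSV))


# --------------------------------------------------------------------------
# primer QC
# --------------------------------------------------------------------------

def qc_filter_primers(primer_table: pd.DataFrame,
                      efficiency_range: tuple[float, float] = (90.0, 115.0),
                      min_r_squared: float = 0.95
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain primers with efficiency in [90, 115] (inclusive), r^2 strictly
    above 0.95 and a single melt peak.

    Rules whose column is absent from the table are recorded as
    ``not evaluated`` and do not reject.  Returns ``(retained, rejected)``;
    rejected rows carry a ``rejection_reason`` column naming every failed
    rule.
    """
    if "efficiency" not in primer_table.columns:
        raise ValueError("primer table must have an 'efficiency' column")
    df = primer_table.copy()
    reasons = []
    lo, hi = efficiency_range
    for _, row in df.iterrows():
        failed = []
        eff = row["efficiency"]
        if not lo <= eff <= hi:
            failed.append(f"efficiency {eff} outside [{lo}, {hi}]")
        if "r_squared" in df.columns and pd.notna(row.get("r_squared")):
            if not row["r_squared"] > min_r_squared:
                failed.append(f"r_squared {row['r_squared']} not > {min_r_squared}")
        if "single_peak" in df.columns and pd.notna(row.get("single_peak")):
            if not bool(row["single_peak"]):
                failed.append("multiple melt peaks")
        reasons.append("; ".join(failed))
    df["rejection_reason"] = reasons
    retained = df[df["rejection_reason"] == ""].drop(columns="rejection_reason")
    rejected = df[df["rejection_reason"] != ""]
    return retained.reset_index(drop=True), rejected.reset_index(drop=True)


# --------------------------------------------------------------------------
# ddCt
# --------------------------------------------------------------------------

def _mean_ct(df: pd.DataFrame, max_replicate_sd: float = 0.5) -> pd.DataFrame:
    reps = df[CT_COLUMNS].to_numpy(dtype=float)
    out = df[["sample", "condition", "plate", "gene"]].copy()
    out["mean_ct"] = np.nanmean(reps, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["ct_sd"] = np.nanstd(reps, axis=1, ddof=1)
    out["replicate_qc_warning"] = out["ct_sd"] > max_replicate_sd
    return out


def relative_expression(ct_table: pd.DataFrame,
                        reference_gene: str = REFERENCE_GENE,
                        control_label: str = "control") -> pd.DataFrame:
    """Per-sample dCt, per-plate ddCt against the control mean, and fold.

    Ct values outside (0, 40] are rejected; samples lacking the reference
    gene are dropped with a warning; a plate without control samples is an
    error.  Returns one row per (sample, gene != reference) with columns
    ``mean_ct``, ``delta_ct``, ``delta_delta_ct``, ``fold_change``.
    """
    required = {"sample", "condition", "plate", "gene", *CT_COLUMNS}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    reps = ct_table[CT_COLUMNS].to_numpy(dtype=float)
    bad = (reps <= 0) | (reps > 40)
    if np.nansum(bad):
        raise ValueError("Ct values must lie in (0, 40]")

    means = _mean_ct(ct_table)
    ref = means[means["gene"] == reference_gene] \
        .set_index(["plate", "sample"])["mean_ct"]
    genes = means[means["gene"] != reference_gene].copy()

    keys = list(zip(genes["plate"], genes["sample"]))
    have_ref = [k in ref.index for k in keys]
    if not all(have_ref):
        dropped = sorted({k[1] for k, ok in zip(keys, have_ref) if not ok})
        warnings.warn(f"samples without reference gene excluded: {dropped}")
        genes = genes[have_ref]
        keys = [k for k, ok in zip(keys, have_ref) if ok]
    genes["delta_ct"] = genes["mean_ct"].to_numpy() - ref.loc[keys].to_numpy()

    control_mean = (genes[genes["condition"] == control_label]
                    .groupby(["plate", "gene"])["delta_ct"].mean())
    for plate in genes["plate"].unique():
        if plate not in control_mean.index.get_level_values(0):
            raise ValueError(f"plate {plate!r} has no {control_label!r} samples")
    idx = pd.MultiIndex.from_arrays([genes["plate"], genes["gene"]])
    genes["delta_delta_ct"] = (genes["delta_ct"].to_numpy()
                               - control_mean.loc[idx].to_numpy())
    genes["fold_change"] = 2.0 ** (-genes["delta_delta_ct"])
    return genes.reset_index(drop=True)


def myh_proportions(expression_records: pd.DataFrame,
                    myh_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-sample proportional Myh composition.

    Each detected Myh gene is linearised as 2^-dCt and expressed as a
    percentage of the sample's total linearised Myh signal.  Undetected
    isoforms (missing mean Ct) are excluded and listed in the
    ``excluded_genes`` frame attribute.  Proportions sum to 100 per sample.
    """
    df = expression_records
    if myh_genes is None:
        myh_genes = sorted(g for g in df["gene"].unique()
                           if g.lower().startswith("myh"))
    sub = df[df["gene"].isin(myh_genes)].copy()
    detected = sub[np.isfinite(sub["mean_ct"])].copy()
    excluded = sorted(set(myh_genes) - set(detected["gene"].unique()))
    if detected.empty:
        raise ValueError("no detectable Myh genes in the records")
    per_sample_n = detected.groupby("sample")["gene"].nunique()
    if (per_sample_n < 2).any():
        raise ValueError("need >= 2 detected Myh genes per sample")
    detected["linear_expression"] = 2.0 ** (-detected["delta_ct"])
    totals = detected.groupby("sample")["linear_expression"].transform("sum")
    detected["myh_proportion_pct"] = 100.0 * detected["linear_expression"] / totals
    out = detected[["sample", "condition", "plate", "gene",
                    "delta_ct", "myh_proportion_pct"]].reset_index(drop=True)
    out.attrs["excluded_genes"] = excluded
    return out


# --------------------------------------------------------------------------
# western blots and viability
# --------------------------------------------------------------------------

def adjusted_relative_density(lanes: pd.DataFrame,
                              control_label: str = "control") -> pd.DataFrame:
    """Adjusted relative density: per-lane band / loading-control ratio,
    normalised to the mean control-lane ratio of the same target."""
    required = {"lane", "condition", "target", "band_density", "loading_density"}
    missing = required - set(lanes.columns)
    if missing:
        raise ValueError(f"blot table missing columns: {sorted(missing)}")
    df = lanes.copy()
    if (df["loading_density"] <= 0).any():
        raise ValueError("loading-control density must be positive")
    df["ratio"] = df["band_density"] / df["loading_density"]
    ctrl = df[df["condition"] == control_label].groupby("target")["ratio"].mean()
    for target in df["target"].unique():
        if target not in ctrl.index or ctrl.loc[target] <= 0:
            raise ValueError(f"target {target!r} lacks positive control lanes")
    df["adjusted_relative_density"] = (
        df["ratio"] / ctrl.loc[df["target"]].to_numpy())
    return df


def viability_fold(readings: pd.DataFrame, control_label: str = "control",
                   blank_label: str = "media") -> pd.DataFrame:
    """Blank-corrected Rfu fold change per condition vs the control mean."""
    required = {"well", "condition", "rfu"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    blanks = readings[readings["condition"] == blank_label]
    if blanks.empty:
        raise ValueError("media-only blank wells are required")
    blank_mean = blanks["rfu"].mean()
    df = readings[readings["condition"] != blank_label].copy()
    df["corrected_rfu"] = df["rfu"] - blank_mean
    means = df.groupby("condition")["corrected_rfu"].mean()
    if control_label not in means.index or means.loc[control_label] <= 0:
        raise ValueError("control mean corrected Rfu must be positive")
    out = means.rename("mean_corrected_rfu").to_frame()
    out["fold_vs_control"] = means / means.loc[control_label]
    return out.reset_index()
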