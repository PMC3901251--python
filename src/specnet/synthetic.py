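"""Synthetic two-class spectral cohorts with hub-structured disease couplings.

The generator emulates the statistical structure the pairwise dual model
assumes.  Most bins are independent baseline intensity plus Gaussian noise,
identically in both classes.  A few *hub* bins, each with a block of
*partner* bins, carry the disease pattern:

* the hub bin reflects a marker metabolite: near baseline in controls,
  displaced by ``hub_shift`` in patients (presence/absence of a compound);
* each partner follows a class-specific linear law on its hub,
  ``partner = slope * hub + intercept + N(0, resid_std)``, with slopes
  differing by 1.0 between the classes and intercepts chosen so that the
  partner bins' *marginal* distribution is identical in the two classes;
* in patients the partner residuals of a hub additionally share a
  per-subject latent factor (``partner_factor_corr``), modelling a common
  pathway response; in controls they fluctuate independently.  The factor
  changes only the correlation structure, not the residual spread.

The two signatures are purely relational or localized at the hubs, so a
patient's reconstructed network is star-like — the hub bins link to most of
the network and dominate the centrality ranking — while control networks
carry only the scattered links that pair-model sampling noise promotes.

``disease_strength`` interpolates every disease-specific quantity between
the control law (0: the class generators are identical) and the full
disease law (1); a series of strengths emulates a patient whose disease
signal decays and rebounds under treatment.

For cohorts emulating *raw* (unbinned) spectra, ``feature_width`` spreads
every hub/partner feature over that many consecutive columns, the way a
real spectral peak spans several adjacent measurements; aggregating such a
spectrum with a matching bin size recovers the feature values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CONTROL, DISEASE, SpectralDataset


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults emulate a 200-bin NMR study with 25 control and 25 disease
    subjects and three hub bins of 30 partners each; the disease coupling
    differs from the control coupling by a slope offset of 1.0 at a
    residual spread of 0.1 intensity units.
    """

    n_bins: int = 200
    m_control: int = 25
    m_disease: int = 25
    hub_bins: list[int] | None = None
    n_hubs: int = 3
    partners_per_hub: int = 30
    control_coupling: tuple[float, float, float] = (-0.5, 2.0, 0.1)
    disease_coupling: tuple[float, float, float] = (0.5, 0.25, 0.1)
    background_noise_std: float = 0.1
    baseline_level: float = 1.0
    hub_shift: float = 1.5
    hub_std: float = 0.1
    partner_factor_corr: float = 0.995
    feature_width: int = 1
    disease_strength: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        problems = []
        if self.n_bins < 2:
            problems.append("n_bins must be >= 2")
        if self.m_control < 3 or self.m_disease < 3:
            problems.append("m_control and m_disease must be >= 3")
        if self.partners_per_hub < 1:
            problems.append("partners_per_hub must be >= 1")
        for name in ("control_coupling", "disease_coupling"):
            if getattr(self, name)[2] <= 0:
                problems.append(f"{name} residual std must be > 0")
        if self.background_noise_std <= 0 or self.hub_std <= 0:
            problems.append("background_noise_std and hub_std must be > 0")
        if not 0.0 <= self.partner_factor_corr <= 1.0:
            problems.append("partner_factor_corr must lie in [0, 1]")
        if self.feature_width < 1:
            problems.append("feature_width must be >= 1")
        if not 0.0 <= self.disease_strength <= 1.0:
            problems.append("disease_strength must lie in [0, 1]")
        if self.hub_bins is not None:
            hubs = list(self.hub_bins)
            if len(set(hubs)) != len(hubs):
                problems.append("hub_bins must be distinct")
            if any(not 0 <= h < self.n_bins for h in hubs):
                problems.append("hub_bins must be valid bin indices")
            if self.feature_width != 1:
                problems.append("explicit hub_bins require feature_width 1")
        elif self.n_hubs < 1:
            problems.append("n_hubs must be >= 1")
        n_hubs = len(self.hub_bins) if self.hub_bins is not None else self.n_hubs
        needed = n_hubs * (1 + self.partners_per_hub) * self.feature_width
        if needed > self.n_bins:
            problems.append(
                f"hubs and partners need {needed} columns but only "
                f"{self.n_bins} exist"
            )
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    def pattern_layout(self) -> dict[int, list[int]]:
        """Resolved hub -> partner assignment (leading column of each feature).

        With explicit ``hub_bins`` each hub takes the next free non-hub
        indices after it (wrapping); otherwise features are spread evenly
        across the axis, each hub immediately followed by its partner block.
        Features occupy ``feature_width`` consecutive columns starting at
        the returned index.
        """
        p = self.partners_per_hub
        if self.hub_bins is None:
            total = self.n_hubs * (1 + p)
            stride = self.n_bins // total
            stride = max(stride - stride % self.feature_width, self.feature_width)
            cols = [k * stride for k in range(total)]
            return {
                cols[h * (1 + p)]: cols[h * (1 + p) + 1 : (h + 1) * (1 + p)]
                for h in range(self.n_hubs)
            }
        hubs = list(self.hub_bins)
        used = set(hubs)
        layout: dict[int, list[int]] = {}
        for h in hubs:
            partners: list[int] = []
            c = h
            while len(partners) < p:
                c = (c + 1) % self.n_bins
                if c not in used:
                    partners.append(c)
                    used.add(c)
            layout[h] = partners
        return layout

    def coupling_at(self, strength: float) -> tuple[float, float, float]:
        """Interpolated (slope, intercept, resid_std) at a disease strength."""
        a, b, s = self.control_coupling
        a2, b2, s2 = self.disease_coupling
        return (
            a + strength * (a2 - a),
            b + strength * (b2 - b),
            s + strength * (s2 - s),
        )


def _draw_subject(
    config: CohortConfig,
    strength: float,
    rng: np.random.Generator,
    layout: dict[int, list[int]],
) -> np.ndarray:
    x = config.baseline_level + rng.normal(
        0.0, config.background_noise_std, config.n_bins
    )
    slope, intercept, resid = config.coupling_at(strength)
    load = strength * config.partner_factor_corr
    w = config.feature_width
    for hub, partners in layout.items():
        hub_value = (
            config.baseline_level
            + strength * config.hub_shift
            + rng.normal(0.0, config.hub_std)
        )
        factor = rng.normal()
        noise = load * factor + np.sqrt(1.0 - load * load) * rng.normal(
            0.0, 1.0, len(partners)
        )
        partner_values = slope * hub_value + intercept + resid * noise
        x[hub : hub + w] = hub_value
        for value, start in zip(partner_values, partners):
            x[start : start + w] = value
    return x


def generate_cohort(config: CohortConfig) -> SpectralDataset:
    """Draw a labeled two-class cohort; deterministic given ``config.seed``.

    Control subjects follow the control law exactly; disease subjects use
    the couplings, hub displacement and factor loading interpolated at
    ``config.disease_strength``.  Each subject draws from its own
    seed-derived substream, so cohorts of different sizes share their
    leading subjects.
    """
    layout = config.pattern_layout()
    m = config.m_control + config.m_disease
    streams = np.random.SeedSequence(config.seed).spawn(m)
    rows = []
    ids = []
    labels = []
    for k in range(config.m_control):
        rows.append(_draw_subject(config, 0.0, np.random.default_rng(streams[k]), layout))
        ids.append(f"control_{k:03d}")
        labels.append(CONTROL)
    for k in range(config.m_disease):
        rng = np.random.default_rng(streams[config.m_control + k])
        rows.append(_draw_subject(config, config.disease_strength, rng, layout))
        ids.append(f"disease_{k:03d}")
        labels.append(DISEASE)
    return SpectralDataset(
        intensities=np.vstack(rows),
        subject_ids=ids,
        labels=np.array(labels, dtype=object),
        bin_axis=np.arange(config.n_bins, dtype=float),
        axis_unit="index",
        provenance=[
            f"synthetic cohort: {config.m_control} control + {config.m_disease} "
            f"disease subjects, {config.n_bins} columns, "
            f"{len(layout)} hubs x {config.partners_per_hub} partners "
            f"(feature width {config.feature_width}), "
            f"disease_strength={config.disease_strength}, seed={config.seed}"
        ],
    )


def generate_trajectory(
    config: CohortConfig,
    strengths: list[float],
    seed: int,
) -> list[tuple[int, np.ndarray]]:
    """One synthetic subject per timepoint, drawn at the given disease strengths."""
    if not strengths:
        raise ValueError("strengths must be non-empty")
    bad = [s for s in strengths if not 0.0 <= s <= 1.0]
    if bad:
        raise ValueError(f"strengths must lie in [0, 1]; got {bad}")
    layout = config.pattern_layout()
    streams = np.random.SeedSequence(seed).spawn(len(strengths))
    return [
        (t, _draw_subject(config, s, np.random.default_rng(streams[t]), layout))
        for t, s in enumerate(strengths)
    ]
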