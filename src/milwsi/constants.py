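"""Fixed appearance constants: procedural texture parameters and the heatmap ramp.

All synthetic textures are procedural (per-class mean colour plus band-pass
spatial noise) so the repository ships no image assets.  The confounder
("necrosis/inflammation") texture is rendered by the *same* generator
whether it occurs inside a carcinoma region or on a non-neoplastic slide;
only where it occurs differs, which is exactly the label-noise mechanism
the training comparison probes.
"""

# Truth-mask class codes (single-channel PNG values).
MASK_BACKGROUND = 0
MASK_NORMAL = 1
MASK_CARCINOMA = 2
MASK_CONFOUNDER = 3

# Mean RGB colour per tissue class, 0-255.  Loosely H&E-like: pale
# background, eosinophilic normal tissue, hyperchromatic carcinoma, and a
# dull granular confounder that is not trivially the carcinoma colour.
BACKGROUND_COLOUR = (245, 244, 246)
NORMAL_COLOUR = (225, 172, 195)
CARCINOMA_COLOUR = (148, 96, 168)
CONFOUNDER_COLOUR = (186, 135, 120)

# Per-slide carcinoma shade: each carcinoma slide mixes the carcinoma mean
# colour toward the normal-tissue colour by a fraction drawn uniformly from
# this range, emulating the between-case variability of tumour appearance
# (well-differentiated tumours resemble normal tissue more closely).
CARCINOMA_SHADE_RANGE = (0.0, 0.6)

# Per-slide stain jitter: one RGB offset (normal, sd in 0-255 units) drawn
# per slide and added to every tissue class on that slide, emulating
# slide-to-slide staining/scanner variation.  Against this variation the
# most normal-shaded carcinomas are genuinely ambiguous, so both training
# regimes have hard positives — as real cohorts do.
STAIN_JITTER_SD = 6.0

# Per-slide confounder shade jitter (0-255 units): necrotic/inflammatory
# lesions vary from case to case far more than ordinary parenchyma, so each
# slide's confounder colour is drawn around the base colour with this sd.
# The draw is identically distributed whether the confounder sits inside a
# carcinoma region or on a benign slide.  Because benign slides carrying
# the confounder are the rarer source of training labels, a fresh
# confounder shade at test time is surrounded mostly by carcinoma-labelled
# neighbours under region-label training.
CONFOUNDER_JITTER_SD = 8.0

# Band-pass noise: white noise smoothed at SIGMA_FINE minus SIGMA_COARSE,
# rescaled to unit variance and multiplied by the cohort's texture_noise_sd.
TEXTURE_SIGMA_FINE = 1.5
TEXTURE_SIGMA_COARSE = 6.0

# Tissue masking: a pixel is background when all channels are near-white.
TISSUE_MIN_CHANNEL_BELOW = 235

# Heatmap rendering.
HEATMAP_COLORMAP = "inferno"
HEATMAP_ALPHA = 0.55
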