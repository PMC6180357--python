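# sfhlogit experiment configuration (consumed by `sfhlogit run <file>` or
# RunConfig.from_yaml).  Every random choice is derived from the seeds
# below, so re-running the same file reproduces the report byte for byte.

# --- data -----------------------------------------------------------------
# Either point csv_path at a dataset (header row, label column "y" in
# {-1,+1}) or leave it null to generate synthetic data.
csv_path: null
synthetic_kind: binary      # "binary" (genomic-style) | "continuous" (financial-style)
n_records: 300
n_covariates: 5
beta_scale: 1.0             # std-dev of the ground-truth coefficients
data_seed: 2

# --- train/test split -----------------------------------------------------
n_train: 200                # first n_train rows train, the rest test
shuffle_seed: null          # set to an int to shuffle before splitting

# --- method ---------------------------------------------------------------
iters: 1                    # SFH iterations (encrypted supports 0 or 1)
inversion: newton           # "exact" | "newton" (division-free reciprocal)
mean_magnitude: null        # reciprocal start constant; null = by covariate kind
tau: 0.5                    # classification threshold

# --- encryption (optional) ------------------------------------------------
encrypted: true
scheme_preset: toy          # "toy" | "full" (D=4096, q=2^186) | "mini"
encoding_preset: toy        # "toy" | "genomic" | "financial"
key_seed: 2
encrypt_seed: 3

# --- output ---------------------------------------------------------------
outdir: scratch/example_run
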