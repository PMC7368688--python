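# Per-class error weighting factors for Argos Least-Squares locations.
#
# K_x (east) and K_y (north) are dimensionless ratios of each quality class's
# location-error standard deviation to that of class 3, per axis. The values
# below derive from standard-error estimates for Argos transmitters deployed
# on captive seals at a known location (Vincent et al. 2002, Marine Mammal
# Science 18:156-166), the standard calibration used by state-space models of
# Least-Squares Argos data. They are data, not constants: override them per
# study via the ls-table configuration option if an independent calibration
# is available. Class Z carries no calibration; the reader's class-Z policy
# (relabel as B, or drop) is applied before these factors are used.
"3": {K_x: 1.0, K_y: 1.0}
"2": {K_x: 1.54, K_y: 1.29}
"1": {K_x: 3.72, K_y: 2.55}
"0": {K_x: 23.9, K_y: 14.99}
"A": {K_x: 13.51, K_y: 22.0}
"B": {K_x: 44.22, K_y: 32.53}
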