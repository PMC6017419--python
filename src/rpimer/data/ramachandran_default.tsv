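# Default 7-code Ramachandran region table (degrees).
# Synthetic stand-in boundaries: round-number rectangles around the
# conventional conformational basins, not a published clustering.
# Replace via rpimer.encode.load_codebook for an exact region set.
# Columns: code, phi_min, phi_max, psi_min, psi_max; [min, max) on the
# torus, min > max wraps the +-180 seam; code 'g' is the fallback for
# points outside every rectangle.
code	phi_min	phi_max	psi_min	psi_max
a	-160	-20	-120	50
b	-180	-100	50	180
c	-100	-20	50	180
d	20	160	-60	90
e	-180	-20	-180	-120
f	20	160	90	180
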