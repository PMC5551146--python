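# BOILED-Egg ellipse model in (tPSA, WLogP) space.
#
# Geometry of the two published best-fit ellipses delimiting the
# physicochemical space of well-absorbed (intestinal, "white") and
# brain-permeant (brain, "yolk") small molecules. tPSA on the abscissa
# (Angstrom^2), WLogP on the ordinate (dimensionless); rotation is the
# counter-clockwise tilt of the tPSA semi-axis, in degrees.
version: 1
rotation_units: degrees
boundary_inclusive: true   # points on the boundary (quadratic form == 1) count as inside
ellipses:
  intestinal:
    center: [71.051, 2.292]
    semi_axis_tpsa: 71.0405
    semi_axis_wlogp: 4.3700
    rotation: -1.031325
    interpretation: "inside => predicted fraction absorbed Fa >= 0.30 (high GI absorption)"
  brain:
    center: [38.117, 3.177]
    semi_axis_tpsa: 41.0305
    semi_axis_wlogp: 2.7785
    rotation: -0.14458
    interpretation: "inside => predicted LogBB >= 0 (brain-permeant)"
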