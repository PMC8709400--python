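# Default visual-model configuration.
#
# Receptor peak sensitivities (lambda_max, nm) per pollinator guild.  The
# curves themselves are generated from an A1 visual-pigment template, so
# every value here can be overridden without touching code.
trim_nm: [325, 700]

guilds:
  bee: # honeybee-like trichromat
    receptors:
      uv: 344
      blue: 436
      green: 556
    luminance_receptor: green
  fly: # R7/R8 inner photoreceptor pairs of the pale and yellow ommatidia
    receptors:
      r7p: 330
      r7y: 350
      r8p: 430
      r8y: 530
    luminance_receptor: r8y
  butterfly: # tetrachromat
    receptors:
      u: 360
      s: 440
      m: 530
      l: 600
    luminance_receptor: l

# Fly color categories by quadrant of the opponent plane
# (cx, cy) = (q_r7p - q_r8p, q_r7y - q_r8y).  The quadrant -> name map is
# a labelling convention, kept here so it can be audited and changed.
fly_quadrants:
  "+,+": Fly UV
  "-,+": Fly Purple
  "-,-": Fly Blue
  "+,-": Fly Yellow

# Hexagon sector labels in angular order; the k-th entry covers the 60
# degree wedge centred at (-30 + 60k) degrees from the positive x axis.
# Pure-green excitation lies at -30 deg, pure blue at +90, pure UV at 210.
hexagon_sectors: [Green, Blue-Green, Blue, UV-Blue, UV, UV-Green]

# Regular tetrahedron with unit circumradius, centroid at the origin;
# the locus of a petal is the relative-catch weighted sum of vertices.
tetrahedron_vertices:
  u: [0.0, 0.0, 1.0]
  s: [0.9428090415820634, 0.0, -0.3333333333333333]
  m: [-0.4714045207910317, 0.816496580927726, -0.3333333333333333]
  l: [-0.4714045207910317, -0.816496580927726, -0.3333333333333333]

# Perceptibility rules: minimum color-space distance for discrimination.
perceptibility:
  bee:
    rule: euclidean_threshold
    threshold: 0.09 # hexagon units
  fly:
    rule: quadrant_change
  butterfly:
    rule: axis_threshold
    threshold: 0.03 # relative-catch units
    axis: u
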