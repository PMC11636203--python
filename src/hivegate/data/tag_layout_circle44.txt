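# Synthetic transcription of a 10x10 circular tag-family cell-role grid
# (44 data bits, Hamming-distance-12 class). Cell roles:
#   w  fixed white (detection border ring, outer)
#   b  fixed black (detection border ring, inner)
#   d  data cell (white = bit 1, black = bit 0)
#   x  ignored (corner trim producing the raster circle)
# Bit significance follows raster scan of the d cells, most significant first.
x x d d d d d d x x
x d w w w w w w d x
d w b b b b b b w d
d w b d d d d b w d
d w b d d d d b w d
d w b d d d d b w d
d w b d d d d b w d
d w b b b b b b w d
x d w w w w w w d x
x x d d d d d d x x
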