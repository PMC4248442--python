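source	type	mtb_call	msm_call	differential
2-oxoglutarate	carbon	Y	NA	false
Oxalomalate	carbon	Y	NA	false
Acetate	carbon	Y	Y	false
Propanoate	carbon	X	Y	true
Acetoacetic acid	carbon	Y	NA	false
Pyruvate	carbon	Y	Y	false
Adenosine	carbon	X	X	false
D-serine	carbon	Y	X	true
D-alanine	carbon	Y	Y	false
D-tagatose	carbon	X	NA	false
L-alanine	carbon	Y	Y	false
D-trehalose	carbon	Y	Y	false
L-asparagine	carbon	Y	Y	false
Tween 20	carbon	Y	Y	false
Butyrate	carbon	Y	Y	false
Tween 40	carbon	Y	Y	false
Caproic acid	carbon	Y	Y	false
Tween 80	carbon	Y	Y	false
Citrate	carbon	Y	Y	false
D-fructose-6-phosphate	carbon	Y	Y	false
D-glucose-6-phosphate	carbon	Y	Y	false
D-glucose	carbon	Y	Y	false
L-glutamate	carbon	Y	Y	false
L-glutamine	carbon	Y	Y	false
Glycerol	carbon	Y	Y	false
Glycine	carbon	Y	NA	false
L-lactate	carbon	Y	Y	false
D-malate	carbon	X	Y	true
L-malate	carbon	Y	Y	false
D-mannose	carbon	X	Y	true
Methyl-pyruvate	carbon	Y	Y	false
Mono methyl-succinate	carbon	Y	Y	false
N-acetyl-glucosamine	carbon	X	Y	true
L-Alanine	nitrogen	Y	Y	false
Allantoin	nitrogen	X	Y	true
L-Asparagine	nitrogen	Y	Y	false
L-Aspartic acid	nitrogen	X	Y	true
L-Cysteine	nitrogen	Y	Y	false
D-Galactosamine	nitrogen	Y	Y	false
D-Glucosamine	nitrogen	X	Y	true
L-Glutamic acid	nitrogen	Y	Y	false
L-Glutamine	nitrogen	Y	Y	false
L-Ornithine	nitrogen	Y	Y	false
D-Serine	nitrogen	Y	Y	false
L-Serine	nitrogen	Y	Y	false
L-Threonine	nitrogen	X	Y	true
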