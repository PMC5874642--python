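# Ramachandran region polygons, general case (v1): rectilinear
# approximation; favoured takes precedence over allowed; boundary
# points belong to the more permissive (better) class.
# name	class	phi	psi
beta-favoured	favoured	-180	90
beta-favoured	favoured	-45	90
beta-favoured	favoured	-45	180
beta-favoured	favoured	-180	180
alpha-favoured	favoured	-160	-75
alpha-favoured	favoured	-45	-75
alpha-favoured	favoured	-45	-10
alpha-favoured	favoured	-160	-10
lalpha-favoured	favoured	45	20
lalpha-favoured	favoured	80	20
lalpha-favoured	favoured	80	75
lalpha-favoured	favoured	45	75
broad-allowed	allowed	-180	-120
broad-allowed	allowed	-20	-120
broad-allowed	allowed	-20	180
broad-allowed	allowed	-180	180
beta-wrap-allowed	allowed	-180	-180
beta-wrap-allowed	allowed	-20	-180
beta-wrap-allowed	allowed	-20	-160
beta-wrap-allowed	allowed	-180	-160
lalpha-allowed	allowed	20	0
lalpha-allowed	allowed	100	0
lalpha-allowed	allowed	100	90
lalpha-allowed	allowed	20	90
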