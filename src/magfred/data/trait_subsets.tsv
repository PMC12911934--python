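subset_name	trait_id
energy	coxA
energy	coxB
energy	ccoN
energy	cydA
energy	nuoA
energy	nuoB
energy	atpA
energy	atpB
energy	sdhA
energy	petB
energy	qoxA
energy	pufM
energy	psbA
energy	rhodopsin
energy	coxL
energy	hydB
energy	hupL
energy	narG
energy	napA
energy	nirS
energy	nirK
energy	norB
energy	nosZ
energy	dsrA
energy	dsrB
energy	soxB
energy	sqr
energy	fccB
energy	amoA
energy	hao
energy	nxrA
energy	mcrA
energy	frdA
energy	rbcL
energy	acsB
energy	aclB
energy	porA
substrate	amyA
substrate	glgP
substrate	malZ
substrate	treA
substrate	susB
substrate	bglX
substrate	celA
substrate	cbhA
substrate	xynA
substrate	xylB
substrate	abfA
substrate	manB
substrate	pulA
substrate	chiA
substrate	nagZ
substrate	pelA
substrate	pglA
substrate	aguA
substrate	uxaC
substrate	fucO
substrate	rhaA
substrate	araA
substrate	galK
substrate	lacZ
substrate	scrK
substrate	fruK
substrate	gntK
substrate	dctA
substrate	prpB
substrate	acnB
substrate	mdh
substrate	ldhA
substrate	adhE
substrate	ackA
substrate	pta
substrate	gcvT
substrate	putA
substrate	ureC
substrate	speB
substrate	betB
substrate	dmdA
substrate	ddhA
substrate	tmm
substrate	gmaS
substrate	mauA
substrate	xoxF
substrate	mxaF
CO	coxL
CO	coxM
CO	coxS
H2	hydB
H2	hupL
H2	hoxH
H2	hybC
H2	echE
N	nifH
N	nifD
N	nifK
N	amoA
N	hao
N	nxrA
N	narG
N	napA
N	nirS
N	nirK
N	norB
N	nosZ
N	nrfA
N	ureC
S	dsrA
S	dsrB
S	aprA
S	sat
S	soxB
S	soxC
S	sqr
S	fccB
S	sdoA
S	tsdA
CAZy	GH13
CAZy	GH3
CAZy	GH5
CAZy	GH9
CAZy	GH10
CAZy	GH16
CAZy	GH18
CAZy	GH23
CAZy	GH29
CAZy	GH43
CAZy	GH73
CAZy	GH77
CAZy	GH109
CAZy	GT2
CAZy	GT4
CAZy	GT28
CAZy	GT41
CAZy	GT51
CAZy	CE1
CAZy	CE4
CAZy	CE10
CAZy	CE11
CAZy	AA3
CAZy	AA7
CAZy	CBM5
CAZy	CBM13
CAZy	CBM44
CAZy	CBM50
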