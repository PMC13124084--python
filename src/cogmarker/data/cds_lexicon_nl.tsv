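Catastrophizing	(zal|gaat)(.+ |)falen, zal(.+ |)fout gaan, zal(.+ |)verkeerd gaan, zal(.+ |)mis gaan, (zal|gaat)(.+ |)mislukken, (zal|gaat)(.+ |)eindigen, (zal|gaat)(.+ |)stoppen, (zal|gaat)(.+ |)ophouden, wordt onmogelijk, zal onmogelijk zijn, (zal|gaat) niet (gebeuren|plaatsvinden), wordt vreselijk, zal vreselijk zijn, wordt verschrikkelijk, zal verschrikkelijk zijn, wordt een ramp, zal(.+ |)een ramp zijn, (zal|gaat) nooit (eindigen|stoppen), (stopt|eindigt) niet, houdt niet op, gaat niet (stoppen|ophouden)
Dichotomous reasoning	alleen, elke, iedere, iedereen, allemaal, alles, overal, altijd, perfect, ideaal, het (aller|)?beste?", alle, niet (één|een), geen enkele, niemand, geen een, niets, niks, nergens, nooit, waardeloos, het (aller|)?ergste?, noch, (of|ofwel)(.+ |)of, zwart[-/]wit, zwart of wit, ooit
Disqualifying the positive	top,? maar, geweldig,? maar, goed,? maar, ok(e|é)?,? maar, niet echt (geweldig|top), niet zo goed, het was niet, niet zo, prima,? maar, acceptabel,? maar, afdoende,? maar
Emotional reasoning	maar ik voel, maar ik heb het gevoel, want ik voel, want ik heb het gevoel, omdat ik voel, omdat ik heb het gevoel, maar het(.+ |)voelt, want het(.+ |)voelt, omdat het(.+ |)voelt, voelt nog steeds
Fortune-telling	ik zal(.+ |) niet, we zullen(.+ |) niet, j(ij|e) (zal|zult)(.+ |) niet, z(ij|e) zullen(.+ |) niet, het zal(.+ |)niet, dat zal(.+ |)niet, hij zal(.+ |)niet, z(e|ij) zal(.+ |)niet
Labeling and mislabeling	ik ben een, hij is een, z(e|ij) is een, z(e|ij) zijn een, (het|'t) is een, d(a|i)t is een, slecht in, waardeloos voor, ik(.+ |)nooit, hij(.+ |)nooit, z(e|ij)(.+ |)nooit, w(e|ij)(.+ |)nooit, j(e|ij)(.+ |)nooit, (een|tot) last, een comple(et|te), een tota(al|le), een enorme?, een gro(te|ot), een loser, een mislukking, een zwak(ke)?, een absolu(ut|te), een volslagen, een slechte, een gebroken, een kapotte, een beschadigde?, een hulpelo(os|ze), een hopelo(os|ze), een incompetente?, een onbekwa(am|me), een giftige?, een toxische?, een lelijke?, een ongewenste?, een onbegeerlijke?, een niet geliefd, een ongeliefde?, een waardelo(os|ze), een vreselijke?, een afschuwelijke?, een verschrikkelijke?
Magnification and minimization	slechtste?, beste?, niet belangrijk, niet relevant, irrelevant, telt niet, onbelangrijk, maakt niet uit, het enige
Mental filtering	ik zie alleen, ik zie slechts, het enige (w|d)at ik zie, kan alleen(maar)? denken, (niks|niets) goeds?, (niks|niets) juist, (compleet|heel) slecht, (compleet|heel) (verkeerd|fout), alleen het (slechte|verkeerde), alleen het slechtste, alleen het ergste, (als|kon) ik maar, ik wou dat ik, als ik nou, (als|kon) het maar, als het nou
Mindreading	iedereen gelooft, iedereen weet, iedereen denkt, iedereen zal(.+ |)geloven, iedereen zal(.+ |)weten, iedereen zal(.+ |)denken, niemand gelooft, niemand weet, niemand denkt, niemand zal(.+ |)geloven, niemand zal(.+ |)weten, niemand zal(.+ |)denken, hij gelooft, hij weet, hij denkt, hij gelooft(.+ |)niet, hij weet(.+ |)niet, hij denkt(.+ |)niet, hij zal(.+ |)geloven, hij zal(.+ |)weten, hij zal(.+ |)denken, hij zal(.+ |)niet geloven, hij zal(.+ |)niet weten, hij zal(.+ |)niet denken, z(ij|e) gelooft, z(ij|e) weet, z(ij|e) denkt, z(ij|e) gelooft(.+ |)niet, z(ij|e) weet(.+ |)niet, z(ij|e) denkt(.+ |)niet, z(ij|e) zal(.+ |)geloven, z(ij|e) zal(.+ |)weten, z(ij|e) zal(.+ |)denken, z(ij|e) zal(.+ |)niet geloven, z(ij|e) zal(.+ |)niet weten, z(ij|e) zal(.+ |)niet denken, z(ij|e) geloven, z(ij|e) weten, z(ij|e) denken, z(ij|e) geloven(.+ |)niet, z(ij|e) weten(.+ |)niet, z(ij|e) denken(.+ |)niet, z(ij|e) zullen(.+ |)geloven, z(ij|e) zullen(.+ |)weten, z(ij|e) zullen(.+ |)denken, z(ij|e) zullen(.+ |)niet geloven, z(ij|e) zullen(.+ |)niet weten, z(ij|e) zullen(.+ |)niet denken, w(ij|e) geloven, w(ij|e) weten, w(ij|e) denken, w(ij|e) geloven(.+ |)niet, w(ij|e) weten(.+ |)niet, w(ij|e) denken(.+ |)niet, w(ij|e) zullen(.+ |)geloven, w(ij|e) zullen(.+ |)weten, w(ij|e) zullen(.+ |)denken, w(ij|e) zullen(.+ |)niet geloven, w(ij|e) zullen(.+ |)niet weten, w(ij|e) zullen(.+ |)niet denken, j(ij|e) gelooft, j(ij|e) weet, j(ij|e) denkt, j(ij|e) gelooft(.+ |)niet, j(ij|e) weet(.+ |)niet, j(ij|e) denkt(.+ |)niet, j(ij|e) (zal|zult)(.+ |)geloven, j(ij|e) (zal|zult)(.+ |)weten, j(ij|e) (zal|zult)(.+ |)denken, j(ij|e) (zal|zult)(.+ |)niet geloven, j(ij|e) (zal|zult)(.+ |)niet weten, j(ij|e) (zal|zult)(.+ |)niet denken
Overgeneralizing	de hele tijd, gebeurt altijd, (steeds|altijd) zo, gebeurt (elke|iedere) keer, compleet”, "helemaal, niemand(.+ |)ooit, z(ij|e)(.+ |)allemaal, jullie(.+ |)allemaal, ik(.+ |)altijd, j(ij|e)(.+ |)altijd, hij(.+ |)altijd, z(ij|e)(.+ |)altijd, ik ben altijd, j(ij|e) bent altijd, hij is altijd, z(ij|e) is altijd, z(ij|e) zijn altijd
Personalizing	(he|al)lemaal mijn, omdat ik, omdat mijn, (door|vanwege) mijn, (door|vanwege) mij, ik ben verantwoordelijk, geef mij de schuld, mij de schuld geven, ik veroorzaakte, ik heb(.+ |)veroorzaakt, ik voel m(ij|e) verantwoordelijk, (he|al)lemaal door mij, allemaal mijn schuld, mijn (fout|schuld), mijn verantwoordelijkheid
Should statements	zou, zouden, moet, moeten
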