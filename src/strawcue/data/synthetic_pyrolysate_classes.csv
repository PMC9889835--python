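compound,group,class
guaiacol,lignin,Arom_C
4-methylguaiacol,lignin,Arom_C
4-vinylguaiacol,lignin,Arom_C
syringol,lignin,Arom_C
4-methylsyringol,lignin,Arom_C
vanillin,lignin,Arom_C
phenol,phenol,Arom_C
2-methylphenol,phenol,Arom_C
4-methylphenol,phenol,Arom_C
2-methoxyphenol,phenol,Arom_C
levoglucosan,carbohydrate,Hete_C
furfural,carbohydrate,Hete_C
5-methylfurfural,carbohydrate,Hete_C
2-furanmethanol,carbohydrate,Hete_C
2(5H)-furanone,carbohydrate,Hete_C
cyclopentanone,carbohydrate,Alic_C
"1,2-cyclopentanedione",carbohydrate,Alic_C
hexadecane,saturated hydrocarbon,Alip_C
heptadecane,saturated hydrocarbon,Alip_C
octadecane,saturated hydrocarbon,Alip_C
nonadecane,saturated hydrocarbon,Alip_C
1-hexadecene,unsaturated hydrocarbon,Alip_C
1-octadecene,unsaturated hydrocarbon,Alip_C
squalene,unsaturated hydrocarbon,Alip_C
pyridine,N-containing,Hete_C
2-methylpyridine,N-containing,Hete_C
pyrrole,N-containing,Hete_C
1H-indole,N-containing,Hete_C
benzonitrile,N-containing,Arom_C
acetamide,N-containing,Alip_C
toluene,aromatic hydrocarbon,Arom_C
ethylbenzene,aromatic hydrocarbon,Arom_C
styrene,aromatic hydrocarbon,Arom_C
xylene,aromatic hydrocarbon,Arom_C
naphthalene,poly-aromatic hydrocarbon,Arom_C
2-methylnaphthalene,poly-aromatic hydrocarbon,Arom_C
phenanthrene,poly-aromatic hydrocarbon,Arom_C
fluorene,poly-aromatic hydrocarbon,Arom_C
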