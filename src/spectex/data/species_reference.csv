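code,abbrev,name,family,training_n,test_n
1,A.a,Acacia auriculiformis,Mimosaceae,60,67
2,A.ca,Areca catechu,Palmae,77,330
3,A.cu,Araucaria cunninghamii,Araucariaceae,59,142
4,A.e,Araucaria excelsa,Araucariaceae,40,159
5,A.h,Artocarpus heterophyllus,Moraceae,73,31
6,A.s,Alstonia scholaris,Apocynaceae,54,31
7,B.,Bambuseae,Poaceae,633,81
8,B.i,Bischofia iavanica,Euphorbiaceae,40,20
9,C.f,Cassia fistula,Caesalpiniaceae,70,69
10,C.g,Cyclobalanopsis glauca,Fagales,55,349
11,C.m,Cerbera manghas,Apocynaceae,32,26
12,C.o,Cananga odorata,Annonaceae,315,41
13,C.si,Cassia siamea,Caesalpiniaceae,89,52
14,C.su,Cassia suratten,Caesalpiniaceae,196,37
15,D.r,Delonix regia,Caesalpiniaceae,274,69
16,D.s,Dalbergia sissoo,Fabaceae,118,94
17,F.e,Ficus eladtica,Moraceae,296,45
18,F.r,Ficus religiosa,Moraceae,164,20
19,H.c,Haematoxylon campechianum,Caesalpiniaceae,262,45
20,H.l,Heritiera littoralis,Palmae,36,16
21,K.f,Koelreuteria formosana,Sapindaceae,47,405
22,L.f,Liquidambar formosana,Hamamelidaceae,89,40
23,L.l,Leucaena leucocephala,Mimosaceae,197,60
24,L.s,Lagerstroemia subcostata,Lythraceae,112,58
25,M.l,Melaleuca leucadendea,Myrtaceae,39,15
26,M.p,Mallotus paniculatus,Euphorbiaceae,75,25
27,P.f,Palaquium formosanum,Sapotaceae,46,55
28,P.r,Plumeria rubra,Apocynaceae,46,180
29,R.m,Ravenala madagascariensis,Strelitziaceae,63,142
30,R.r,Roystonea regia,Palmae,38,34
31,S.c,Spathodea campanulata,Bignoniaceae,189,758
32,S.f,Syzygium formosanum,Myrtaceae,108,27
33,S.l,Sapindus longana,Sapindaceae,183,52
34,S.m,Swietenia macrophylla,Meliaceae,150,64
35,T.ca,Terminalia catappa,Combretaceae,371,134
36,T.ch,Tabebuia chrysantha,Bignoniaceae,58,56
37,T.g,Tectona grandis,Verbenaceae,45,25
38,T.o,Trema orientalis,Ulmaceae,340,48
39,U.p,Ulmus parvifolia,Ulmaceae,414,59
40,Z.s,Zelkova serrata,Ulmaceae,122,141
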