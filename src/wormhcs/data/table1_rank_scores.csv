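rank_score,overall_rank_order,compound,direction,dose_tested,dose_dependent
2.0,1,ivermectin,decrease,True,False
2.5,2,cantharidin,decrease,True,True
10.5,3,"L-655,240",decrease,False,
24.0,4,GR 125487 sulfamate salt,decrease,False,
28.0,5,muscimol hydrobromide,decrease,False,
34.5,6,DL-homatropine hydrobromide,decrease,False,
36.5,7,L(-)-norepinephrine bitartrate,decrease,True,False
41.5,8,N-(2-[4-(4-Chlorophenyl)piperazin-1-yl]ethyl)-3-methoxybenzamide,decrease,False,
51.0,9,cefmetazole sodium,decrease,True,False
52.5,10,HA-100,decrease,False,
56.0,11,SB 206553 hydrochloride,decrease,False,
57.5,12,"L-701,324",decrease,False,
57.5,13,phenamil methanesulfonate,decrease,True,False
58.0,14,rolipram,decrease,False,
61.0,15,doxepin hydrochloride,decrease,True,False
61.5,16,beta-chloro-L-alanine hydrochloride,decrease,False,
65.0,17,S(-)-UH-301 hydrochloride,decrease,False,
72.5,18,L-alpha-methyl DOPA,decrease,False,
73.5,19,taxol,decrease,True,True
74.0,20,cis-(Z)-flupenthixol dihydrochloride,decrease,False,
75.5,21,10-(alpha-diethylaminopropionyl)-phenothiazine hydrochloride,decrease,False,
79.0,22,cantharidic acid,decrease,True,True
81.0,23,fluphenazine dihydrochloride,decrease,True,True
83.5,24,tamoxifen citrate,decrease,True,True
85.0,25,indirubin-3'-oxime,decrease,False,
89.5,26,"(-)-bicuculline methbromide, 1(S), 9(R)",decrease,False,
90.0,27,cephradine,decrease,False,
93.0,28,indatraline hydrochloride,decrease,False,
95.5,29,5-carboxamidotryptamine maleate,decrease,False,
98.0,30,tyrphostin AG 112,decrease,False,
103.5,31,prochlorperazine dimaleate,decrease,False,
105.5,32,B-HT 933 dihydrochloride,decrease,True,False
107.5,33,pimozide,decrease,True,True
1263.0,1,GW2974,increase,False,
1256.0,2,thapsigargin,increase,True,True
1255.0,3,SB 224289 hydrochloride,increase,False,
1255.0,4,clotrimazole,increase,False,
1253.5,5,IC 261,increase,False,
1245.5,6,tetradecylthioacetic acid,increase,False,
1245.0,7,tyrphostin 1,increase,False,
1240.5,8,(+)-bromocriptine methanesulfonate,increase,False,
1238.0,9,"L-162,313",increase,False,
1236.5,10,tyrphostin AG 879,increase,True,True
1236.5,11,IIK7,increase,False,
1234.0,12,glipizide,increase,True,False
1233.5,12,"WIN 62,577",increase,False,
1231.0,14,"(R)-(+)-WIN 55,212-2 mesylate",increase,False,
1229.5,15,rottlerin,increase,True,True
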