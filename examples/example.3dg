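chr1	0	2.73956049	-0.611215602	3.5859792
chr1	100000	3.11173325	-1.38322219	3.07071881
chr1	200000	2.52391406	-0.777242842	3.60668303
chr1	300000	2.57794333	0.145116237	3.98922004
chr1	400000	1.93636159	0.420440156	3.27328037
chr1	500000	2.9134182	0.364910047	3.06766715
chr1	600000	2.42976537	1.23326064	2.95790745
chr1	700000	1.87251518	0.775138433	3.65043635
chr1	800000	2.82893003	0.593642021	3.4216795
chr1	900000	2.29422803	0.998380859	4.16348827
chr1	1000000	2.19787722	0.287967856	3.46632983
chr1	1100000	2.77502268	0.947313888	3.94816582
chr1	1200000	1.84350402	1.27227174	4.11149178
chr1	1300000	2.2332165	0.372727301	3.91414949
chr1	1400000	1.67305794	-0.388101152	3.5864874
chr1	1500000	2.42791746	-0.825296151	4.07541237
chr1	1600000	1.45153033	-1.01959368	4.16984035
chr1	1700000	1.34011678	-1.76253945	3.50982626
chr1	1800000	0.468528099	-1.29125923	3.64483779
chr1	1900000	1.30313834	-1.80769224	3.83646945
chr1	2000000	0.520699123	-2.23684534	3.3852306
chr1	2100000	-0.349719045	-1.88239171	3.04356579
chr1	2200000	-0.330680376	-1.14982494	3.72399466
chr1	2300000	0.506551512	-1.27374594	3.19137251
chr1	2400000	0.470712104	-2.03233128	2.54078523
chr1	2500000	-0.305488127	-2.61754596	2.77538487
chr1	2600000	-0.861625751	-2.84981022	3.57335997
chr1	2700000	-1.14847914	-2.25598412	2.82163815
chr1	2800000	-1.34804693	-3.1788621	2.49229194
chr1	2900000	-0.921361387	-4.05594828	2.71288041
chr1	3000000	-0.771022702	-4.43167545	1.79842572
chr1	3100000	-0.757531318	-3.44274672	1.65064899
chr1	3200000	-1.72117348	-3.27395534	1.85778001
chr1	3300000	-0.88970023	-2.76308203	2.07609332
chr1	3400000	-0.154705682	-3.36017943	1.75475595
chr1	3500000	-0.698270317	-3.58885667	0.947139579
chr1	3600000	-0.305578183	-3.72624937	0.0377902883
chr1	3700000	-1.05587564	-3.49462916	0.656987993
chr1	3800000	-0.494456897	-2.67534148	0.773507062
chr1	3900000	-0.912744688	-3.57657905	0.88667141
chr2	0	-1.68431003	0.206724025	-0.610885397
chr2	100000	-1.81387462	1.18770581	-0.466359466
chr2	200000	-1.89417875	0.663437169	-1.31411747
chr2	300000	-2.1592857	0.634118032	-0.350344317
chr2	400000	-2.04191862	1.51948889	-0.800170304
chr2	500000	-2.74240751	0.948952474	-1.22889343
chr2	600000	-1.86673303	0.611025493	-0.883930296
chr2	700000	-2.53396033	1.29942092	-0.599466832
chr2	800000	-2.7661901	1.23898681	-1.5702485
chr2	900000	-2.44326292	0.90960844	-2.45750716
chr2	1000000	-3.07009161	0.994262856	-1.6829625
chr2	1100000	-2.61084769	0.653720441	-0.862520013
chr2	1200000	-1.66896709	0.811937782	-1.15887826
chr2	1300000	-1.09891608	1.03286839	-0.367530353
chr2	1400000	-0.999612725	0.369271069	-1.10900013
chr2	1500000	-0.309856282	1.0894173	-1.18400312
chr2	1600000	-0.514438946	1.86967842	-1.77505179
chr2	1700000	-1.27882263	2.41928572	-2.11217106
chr2	1800000	-1.29247747	1.98354858	-1.21220067
chr2	1900000	-0.384683072	2.04197383	-0.796874518
chr2	2000000	-1.30929003	2.02000232	-1.17716287
chr2	2100000	-2.10127906	1.44937581	-1.39427746
chr2	2200000	-1.53316573	0.626644839	-1.37527745
chr2	2300000	-1.95028776	0.344347659	-0.511380748
chr2	2400000	-1.57913606	1.26678465	-0.617947187
chr2	2500000	-2.48268825	0.976145567	-0.303110154
chr2	2600000	-2.32251505	-0.007524391	-0.221025076
chr2	2700000	-2.25002438	0.792084429	0.375104808
chr2	2800000	-2.74661034	0.624827873	-0.476615583
chr2	2900000	-3.17485861	0.85363385	0.397599063
chr2	3000000	-3.48377245	0.576471094	-0.512210284
chr2	3100000	-3.61954012	-0.310263727	-0.954102234
chr2	3200000	-4.0654245	-0.358196308	-1.84790847
chr2	3300000	-4.369424	0.150946773	-1.0427019
chr2	3400000	-3.50748991	-0.341103271	-1.1649982
chr2	3500000	-2.70348705	0.108576739	-1.55405769
chr2	3600000	-2.79895383	-0.872247988	-1.72396634
chr2	3700000	-3.20366277	-0.519524103	-2.56764669
chr2	3800000	-2.78558553	0.378373756	-2.42983937
chr2	3900000	-1.7968114	0.527791455	-2.42960214
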