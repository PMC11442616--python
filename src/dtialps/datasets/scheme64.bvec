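0.0 0.1660336334069256 -0.13665093221722485 -0.07715745196942514 0.16813062737188592 0.20133303388438256 -0.3813865975127973 -0.1551916593171578 0.4230339416459823 -0.4403939468437626 -0.16873650236563512 0.47174601082981266 0.11604951385979917 0.5011480503719193 -0.03902759279517935 -0.4869173081717305 -0.4178952630651008 -0.6457703717372939 0.44109403390056273 0.27791336553796797 0.6846299770595812 -0.6750770673798234 -0.26146386116098524 0.7004259372447548 -0.2962894442222964 -0.7405283726267886 0.02543069318390592 0.5920399342659988 0.7746637654409886 0.3495527316038994 0.044128054237517506 -0.6178719845991857 -0.8461336846674056 -0.5608378892746535 0.6488766938815566 0.8739920596652218 0.35973359672539995 -0.8397134884522057 -0.310025968878487 0.858906136462769 -0.4914449564263135 -0.1814141547153935 -0.9157321340754385 -0.77986662927041 0.6328059885269773 -0.02010604589237331 0.8330714138153625 0.9431693582333516 0.28146585546335373 0.5601849980313299 0.16323376787294902 -0.7695328911488912 -0.9641976868913622 -0.5548320920991517 0.9755588312198709 0.802736879163673 0.46106444028860183 -0.2646274541971272 -0.925168694027036 -0.3626241480912769 -0.6308796769829923 -0.9117158342638001 -0.9938585176830328 -0.05488923446854745 -0.7372305658723012
0.0 -0.006103106193477 -0.10839184189808397 0.20664792587101113 -0.35667870664869317 0.34267137134031905 0.15605452566271621 -0.39634650672730265 -0.12262901220953637 -0.1731230945843832 0.47262259454553374 0.19378511375294766 0.6152023360423907 -0.37993025056841623 -0.6372610182659637 0.42255344410834805 -0.49216810269478467 0.08038510626170442 0.5080353472523091 -0.620596393727518 -0.043677381390843144 -0.26395782728355544 0.6881442043024051 0.29130705215308644 -0.7451786836468487 0.3388869273354482 0.8215051153960975 -0.5730364873142357 -0.2937205277549816 0.7571273041228541 -0.838017241155233 -0.574216508418121 -0.00805967207788196 0.638140196461474 0.5793180344150892 0.051845283156984015 -0.8059702213015214 -0.33805703877091714 0.853874345665098 0.36014377830875816 -0.801310562227505 -0.9261581030001859 0.2354440743425804 0.5427944813216029 -0.7139920041309515 0.9551096710712258 -0.4722903544195058 -0.17766093235857167 0.9199070693482467 0.7821571992215167 -0.953788765294318 -0.5907251977961927 -0.11079959087766475 0.8014361020577319 0.15220940055077067 0.577144590335164 -0.8797926306541558 0.9595839636355658 -0.37460846452816404 -0.9309038927440816 -0.7749135680274725 0.4099405318422604 0.10746864246165617 -0.9982359072660891 0.6756337731234818
0.0 0.9861012040721205 0.9846713824084177 0.9753683213734159 0.9189735536798388 0.9176281058962041 0.9111483129863086 0.9048894935203146 0.8977774833331348 0.8809549169536998 0.8649600429467595 0.8601761627445367 0.7797811206107069 0.7774983191695303 0.769659172360884 0.7644345111747436 0.7636321809598953 0.7592883916388896 0.739821694193645 0.7332286664798093 0.7275809789062907 0.6889101672305339 0.6768265681781405 0.6515701863964356 0.5974289034527813 0.5803217898854555 0.569633764117113 0.5666726572200864 0.5600216978726128 0.5518796364968648 0.5438564317499452 0.537130907793962 0.5329097760007379 0.5274826552731975 0.493304825780955 0.483166582305229 0.4701103506222599 0.42496905281310327 0.41806997074168833 0.3641108453370916 0.34114987566431687 0.3306358612068515 0.3255775583153861 0.3117405838148462 0.2996197572281612 0.29556938803737565 0.2879823616230179 0.28083474643136835 0.2730347156890538 0.2728055785474185 0.25227312227889165 0.24261671444621816 0.24092793788742908 0.22329694107933326 0.15848427433942655 0.15005873742445838 0.1156914385250636 0.09576495819768659 0.06108507097613813 0.04383685316022467 0.038727190148101116 0.026888620372708956 0.026376840529785107 0.022632838622338936 0.0031776341095507946
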