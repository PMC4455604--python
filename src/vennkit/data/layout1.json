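{"n":1,"canvas":[700.0,700.0],"curves":{"A":[[570.0,350.0],[569.74,360.79],[568.94,371.56],[567.62,382.28],[565.77,392.92],[563.41,403.46],[560.53,413.86],[557.14,424.12],[553.25,434.19],[548.88,444.06],[544.02,453.71],[538.7,463.1],[532.92,472.23],[526.71,481.05],[520.06,489.57],[513.01,497.74],[505.56,505.56],[497.74,513.01],[489.57,520.06],[481.05,526.71],[472.23,532.92],[463.1,538.7],[453.71,544.02],[444.06,548.88],[434.19,553.25],[424.12,557.14],[413.86,560.53],[403.46,563.41],[392.92,565.77],[382.28,567.62],[371.56,568.94],[360.79,569.74],[350.0,570.0],[339.21,569.74],[328.44,568.94],[317.72,567.62],[307.08,565.77],[296.54,563.41],[286.14,560.53],[275.88,557.14],[265.81,553.25],[255.94,548.88],[246.29,544.02],[236.9,538.7],[227.77,532.92],[218.95,526.71],[210.43,520.06],[202.26,513.01],[194.44,505.56],[186.99,497.74],[179.94,489.57],[173.29,481.05],[167.08,472.23],[161.3,463.1],[155.98,453.71],[151.12,444.06],[146.75,434.19],[142.86,424.12],[139.47,413.86],[136.59,403.46],[134.23,392.92],[132.38,382.28],[131.06,371.56],[130.26,360.79],[130.0,350.0],[130.26,339.21],[131.06,328.44],[132.38,317.72],[134.23,307.08],[136.59,296.54],[139.47,286.14],[142.86,275.88],[146.75,265.81],[151.12,255.94],[155.98,246.29],[161.3,236.9],[167.08,227.77],[173.29,218.95],[179.94,210.43],[186.99,202.26],[194.44,194.44],[202.26,186.99],[210.43,179.94],[218.95,173.29],[227.77,167.08],[236.9,161.3],[246.29,155.98],[255.94,151.12],[265.81,146.75],[275.88,142.86],[286.14,139.47],[296.54,136.59],[307.08,134.23],[317.72,132.38],[328.44,131.06],[339.21,130.26],[350.0,130.0],[360.79,130.26],[371.56,131.06],[382.28,132.38],[392.92,134.23],[403.46,136.59],[413.86,139.47],[424.12,142.86],[434.19,146.75],[444.06,151.12],[453.71,155.98],[463.1,161.3],[472.23,167.08],[481.05,173.29],[489.57,179.94],[497.74,186.99],[505.56,194.44],[513.01,202.26],[520.06,210.43],[526.71,218.95],[532.92,227.77],[538.7,236.9],[544.02,246.29],[548.88,255.94],[553.25,265.81],[557.14,275.88],[560.53,286.14],[563.41,296.54],[565.77,307.08],[567.62,317.72],[568.94,328.44],[569.74,339.21]]},"anchors":{"A":[350.0,355.39]},"name_positions":{"A":[350.0,337.39]}}
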